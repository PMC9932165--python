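protein_id	class	intensity
MaSp1c	MaSp	37.7
MaSp1b	MaSp	12.2
SpiCE-DS1	SpiCE-DS	11.9
MaSp1a	MaSp	10.4
MaSp-like	MaSp	7.2
MaSp2a	MaSp	3.71
MaSp2b	MaSp	2.474
MaSp2c	MaSp	1.855
MaSp2d	MaSp	1.484
MaSp2e	MaSp	1.237
MiSp	MiSp	1.06
SpiCE-DS2	SpiCE-DS	0.928
SpiCE-DS3	SpiCE-DS	0.825
SpiCE-DS4	SpiCE-DS	0.742
SpiCE-DS5	SpiCE-DS	0.675
SpiCE-DS6	SpiCE-DS	0.618
SpiCE-DS7	SpiCE-DS	0.571
SpiCE-DS8	SpiCE-DS	0.53
SpiCE-DS9	SpiCE-DS	0.495
SpiCE-DS10	SpiCE-DS	0.464
SpiCE-DS11	SpiCE-DS	0.437
SpiCE-DS12	SpiCE-DS	0.412
SpiCE-DS13	SpiCE-DS	0.391
SpiCE-DS14	SpiCE-DS	0.371
SpiCE-DS15	SpiCE-DS	0.353
GDH	GDH	0.337
mucin-19	mucin-19	0.323
venom protein	venom protein	0.308
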