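>MaSp1_NTD type=MaSp1 terminus=N
ERHLQRQFIKCSRHPMEMQSEQREPKAFAEYQSMVDMRKQEQCAWWSLCEVNHDYLQEYP
PTVALYSASHEKEKLCGGGIHCWSLQTAQEDRRIEGGLMLSVPQELQLLQLKAASDEMKC
HMRLSKAFEEVPVQ
>MaSp1_CTD type=MaSp1 terminus=C
DLQEFFLWKLSSLYAPLSGCQTLYSQTYTAKMISCILHTLDKQARDPLAFEIFCLKLLAQ
AHSGQHKSWEANERLIKMRPKEKDAAQKKIANDAKNEEMVPQAASYGKPYHQYMENQFPH
DTMQYSA
>MaSp2_NTD type=MaSp2 terminus=N
SVSCLSDTTFKREADKKRACASRTQSTMAFSLKSQEYSQKPLHKKASPEPFMLFQHRTDD
AQQEKMFGVVLQQGIAWNWWKQQHLPWEAIWWPMMGAWEPFEEGQWKQLQLLYAQIWLTC
LK
>MaSp2_CTD type=MaSp2 terminus=C
DEKCVGADECDAQMNSPIHIIKYMTTKHREYKKDDMMTYVDRQAAAAADWQALWETWDKF
TRTMDDKPALCAGPAEVQKAKQDYGALVPYQPPNTEELLAHKQTCKCKQIL
>MiSp_NTD type=MiSp terminus=N
TSAQAHKGADLFGIQSANIHAYNLDGDNVSSARLSDVKRQNPHQCIIVKETMWALDEGLP
SDESMDKVGDFVMNKGAKIMVDKSFLPGYMQFLLQFMPFSHQTAMQQADQKFYNANDDGT
AEDTSKFFKWE
>MiSp_CTD type=MiSp terminus=C
LRKQASVNAKKHWYDALIHDFKSYLEFMRAALFTELWSDQKYDFIDIKWSFEGFIESWAC
LACFKRLRFCEELLAVEVDRTTAYWSWLLIADNCMAHLKILHTEAKEELDRIPGRKQAMK
CWYWKGARKPLDKKQTD
>FlSp_NTD type=FlSp terminus=N
MNQKRLMDLQESCEHMEHSDCQDHACEQHDGWKKDIVCRLHLAWKWKHDLNTKNRHFVAR
SPYLFVACQNEEDKMIGTCESMRLWHKTELKIKCARSSSAGHRINMLSVVWFWDAEPSGA
KQYTTQALNDKAPLHES
>FlSp_CTD type=FlSp terminus=C
SCLWNAQKPMMDQEFAHEKPPMDMWHADQGSQYWNLLAQSAEKRYDINNAWLGGILSARL
HSQRCQNRTGCWTKWKKHHQLIQEEKLADDSAALKDQDLPYKQEDQLSSAPNDQERDCSG
QC
>TuSp_NTD type=TuSp terminus=N
KRDMEAKPWIKKTSARYPYDKDSDFMKTKKKAEGPLKNRLCQASHKPHCMDKMSMYSAAL
CLLLQHMSLYWKQTCLSPLSLSATPTQAEKAYKDRKPQNEKQEKDRPLILQNQHPLECEM
PTTGENTCQDSM
>TuSp_CTD type=TuSp terminus=C
GCSETKPAIDKTQQQVDWFIVHQSDDFKEQEGQNKQSYDKDWSAVRAEIETFHKLNQMVT
TESMQAELIQNDTQQDNDRDFLAVKALMHIWIKLECDLPCQDLMGKIEAVIALEEMNCKS
>AgSp_NTD type=AgSp terminus=N
EDFMLGTTEMEVPGLIIPPPLLKQDQGMMLSTLNMAYGSCNVNDKFLLGLPQKWSLLQSH
IFEFFVDTLVSAWNAKDVENVQCIARLWTREGVQPDLPVFKWMEIQQWRDNDSH
>AgSp_CTD type=AgSp terminus=C
IELKSCFEDLTRNDTTGDDSDYKDMPEEYSFEPQKGTEQSFNAEDTNKGSDQPLADNYPE
HETILLWTRSMDSGSSKCRPVFNESSEAFSQIWKQCRTDAMDLGREDSNYLQNQTVGMKR
DNPLKASVYFFY
>AcSp_NTD type=AcSp terminus=N
KMKGPCFWSKLVRALCGKAEERANYQAWTCSWCKWDLAIAFYNLMDLYSILKPLLIAHDK
AQVQVFMGMTLWQRHNDETDKCEMAELWPAWDKSLSDARPYESDTHWAVACVDTLTS
>AcSp_CTD type=AcSp terminus=C
ELLKYFTDQVWFGELSEKRGDDEYNSGECPKCEQAGMATKQQWSMSSQMQNFTACSYKRD
GHQVMDQRITIERRQHLRADKPQFKHSPCRVQKMIETQPMVIPDGGEDMLSVPYVQSRN
>PySp_NTD type=PySp terminus=N
DLEIWKFKKKRSLVSKSRSMQAKMCNEYEEAGWARRVLRWEPQYKAAHLDSLNAMRQAPM
MQGLWRSGLDSPVACMQGKFVLLYQLQTLLPLCSGEWQSPMAHQAAAQQKHMLEDNDAHL
HADKAWDQLGA
>PySp_CTD type=PySp terminus=C
FSTEASKHDDAVGVLIWMDVGHETSASQEFSQKELFPMDMQIIESTWYDNAQIGYFDHSR
CNPWARLWHAAKRKKKLDKKKWPWKKQLAWCCDPPAIPNMRVRTTVRGDLVLKTRDIHTF
SLNQYKQGPNCQNTTGYC
>other_NTD type=other terminus=N
SCLQDEMMLPEHPGAFIMIEHGKLLTNSFENDGDWSKWQQQDDLEQKELDLGQHDHSECL
RYLQFCLEMHYWSSLVRFANDELCLSWLCGDLTLQKHSETHWLAFLDQDLTKVYRSKSAH
YLKKMMIEKDKFA
>other_CTD type=other terminus=C
PKLWCAYNLKNLITFKQPREVWTLHLIKGTIHSLVSKSELSLWNSVFPVMPFDVLSGGSE
LAHYQLHASGGLIQTIKWDLMEALNFDHWQDQDCRDHYRWATAKEDINDNGQYETMMDAN
GSNVRGIGHASPDAKESDG
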