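name	category	intensity
metabolite_001	organic acids	34789.7
metabolite_002	organic acids	4628.7
metabolite_003	organic acids	67892.2
metabolite_004	organic acids	90295.9
metabolite_005	organic acids	1180.2
metabolite_006	organic acids	3123.6
metabolite_007	organic acids	26682.4
metabolite_008	organic acids	13706.6
metabolite_009	organic acids	21478.3
metabolite_010	organic acids	6126.8
metabolite_011	organic acids	82379.9
metabolite_012	organic acids	70734.4
metabolite_013	organic acids	24319.8
metabolite_014	organic acids	119474.9
metabolite_015	organic acids	44412.0
metabolite_016	organic acids	6069.7
metabolite_017	organic acids	38297.0
metabolite_018	organic acids	5227.4
metabolite_019	organic acids	82262.9
metabolite_020	organic acids	20437.2
metabolite_021	organic acids	16692.4
metabolite_022	organic acids	7931.6
metabolite_023	organic acids	137834.9
metabolite_024	organic acids	17469.4
metabolite_025	organic acids	11585.5
metabolite_026	organic acids	12988.2
metabolite_027	organic acids	48945.6
metabolite_028	organic acids	38107.5
metabolite_029	organic acids	40908.7
metabolite_030	organic acids	42033.9
metabolite_031	organic acids	547146.2
metabolite_032	organic acids	11972.6
metabolite_033	organic acids	10215.2
metabolite_034	organic acids	6498.6
xanthurenic acid	organoheterocyclic compounds	55490.6
metabolite_036	organoheterocyclic compounds	119785.6
metabolite_037	organoheterocyclic compounds	18565.8
metabolite_038	organoheterocyclic compounds	6246.4
metabolite_039	organoheterocyclic compounds	6395.0
metabolite_040	organoheterocyclic compounds	58447.8
metabolite_041	organoheterocyclic compounds	67163.2
metabolite_042	organoheterocyclic compounds	49748.3
metabolite_043	organoheterocyclic compounds	8117.2
metabolite_044	organoheterocyclic compounds	31202.1
metabolite_045	organoheterocyclic compounds	26239.7
metabolite_046	organoheterocyclic compounds	30577.9
metabolite_047	organoheterocyclic compounds	81401.0
metabolite_048	organoheterocyclic compounds	30803.8
metabolite_049	organoheterocyclic compounds	60984.2
metabolite_050	organoheterocyclic compounds	24376.3
metabolite_051	organoheterocyclic compounds	33985.2
metabolite_052	organoheterocyclic compounds	56779.6
metabolite_053	organoheterocyclic compounds	2475.7
metabolite_054	organoheterocyclic compounds	13636.3
metabolite_055	organoheterocyclic compounds	10877.4
metabolite_056	organoheterocyclic compounds	8448.0
metabolite_057	lipids	14578.3
metabolite_058	lipids	207401.5
metabolite_059	lipids	6010.4
metabolite_060	lipids	94128.6
metabolite_061	lipids	1764.6
metabolite_062	lipids	13328.7
metabolite_063	lipids	28117.0
metabolite_064	lipids	53068.2
metabolite_065	lipids	64012.9
metabolite_066	lipids	72404.3
metabolite_067	lipids	13054.8
metabolite_068	lipids	11009.0
metabolite_069	lipids	79774.9
metabolite_070	lipids	16531.8
metabolite_071	lipids	3250.2
metabolite_072	lipids	4024.2
metabolite_073	benzenoids	5545.9
metabolite_074	benzenoids	46431.9
metabolite_075	benzenoids	27272.6
metabolite_076	benzenoids	62052.0
metabolite_077	benzenoids	11604.2
metabolite_078	benzenoids	27939.9
metabolite_079	benzenoids	56296.4
metabolite_080	benzenoids	13849.2
metabolite_081	benzenoids	43702.6
metabolite_082	benzenoids	8160.9
metabolite_083	benzenoids	12777.2
metabolite_084	benzenoids	12424.1
metabolite_085	benzenoids	3663.7
metabolite_086	organic oxygens	45727.7
metabolite_087	organic oxygens	10893.2
metabolite_088	organic oxygens	22443.2
metabolite_089	organic oxygens	45302.6
metabolite_090	organic oxygens	43036.2
metabolite_091	organic oxygens	59759.2
metabolite_092	organic oxygens	19001.5
metabolite_093	organic oxygens	11673.2
metabolite_094	organic nitrogens	19544.0
metabolite_095	organic nitrogens	1752.9
metabolite_096	organic nitrogens	2513.2
metabolite_097	organic nitrogens	3028.9
metabolite_098	organic nitrogens	4935.1
metabolite_099	nucleosides	40121.2
metabolite_100	nucleosides	5663.4
metabolite_101	nucleosides	12490.9
metabolite_102	nucleosides	154638.0
metabolite_103	nucleosides	12908.0
metabolite_104	organooxygens	66587.6
metabolite_105	organooxygens	5429.3
metabolite_106	organooxygens	16185.1
metabolite_107	phenylpropanoids and polyketides	5297.4
metabolite_108	phenylpropanoids and polyketides	13246.0
metabolite_109	alkaloids	77688.5
metabolite_110		607.3
metabolite_111		15547.2
metabolite_112		11575.0
metabolite_113		3323.5
metabolite_114		926.0
metabolite_115		9029.0
metabolite_116		3662.0
metabolite_117		11487.5
metabolite_118		8373.1
metabolite_119		89560.4
metabolite_120		5658.8
metabolite_121		1745.4
metabolite_122		10603.2
metabolite_123		11271.1
metabolite_124		62241.8
metabolite_125		28358.1
metabolite_126		13839.8
metabolite_127		72762.4
metabolite_128		1362.2
metabolite_129		3103.8
metabolite_130		2018.6
metabolite_131		4515.6
metabolite_132		1027.6
metabolite_133		21009.4
metabolite_134		5806.1
metabolite_135		892.3
metabolite_136		1766.3
metabolite_137		12968.4
metabolite_138		28486.6
metabolite_139		161958.7
metabolite_140		641005.7
metabolite_141		15087.4
metabolite_142		1836.6
metabolite_143		330.9
metabolite_144		12107.3
metabolite_145		2393.7
metabolite_146		4345.8
metabolite_147		3235.2
metabolite_148		6560.4
metabolite_149		40093.5
metabolite_150		10255.5
metabolite_151		6387.2
metabolite_152		1713.9
metabolite_153		657.2
metabolite_154		3907.1
metabolite_155		7475.1
metabolite_156		114908.9
metabolite_157		9851.8
metabolite_158		35387.3
metabolite_159		3831.7
metabolite_160		1370.0
metabolite_161		1905.2
metabolite_162		2730.3
metabolite_163		197344.2
metabolite_164		2363.5
metabolite_165		28502.1
metabolite_166		2091.4
metabolite_167		32773.0
metabolite_168		14435.2
metabolite_169		6406.3
metabolite_170		7622.5
metabolite_171		3034.6
metabolite_172		15821.2
metabolite_173		4095.0
metabolite_174		1289.0
metabolite_175		1191.6
metabolite_176		10497.4
metabolite_177		86563.8
metabolite_178		10300.9
metabolite_179		6782.1
metabolite_180		12440.8
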