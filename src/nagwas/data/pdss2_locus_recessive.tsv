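SNP	CHR	POS	A0	A1	BETA	SE	P	BETA_REP	SE_REP	P_REP
6:107541346:I	6	107500000	S	L	0.086	0.014	1.05e-09	0.025	0.014	0.084
6:107546337:D	6	107500000	L	S	0.086	0.014	2.30e-09	0.024	0.015	0.112
rs12191399	6	107500000	T	C	0.086	0.014	9.84e-10	0.025	0.014	0.083
rs2216084	6	107600000	C	T	0.082	0.014	9.25e-09	0.037	0.014	0.01
rs4945774	6	107500000	C	A	0.086	0.014	1.04e-09	0.025	0.014	0.084
rs4946824	6	107500000	T	C	0.086	0.014	1.27e-09	0.026	0.015	0.085
rs6568476	6	107500000	T	C	0.084	0.014	2.75e-09	0.025	0.014	0.089
rs6568477	6	107500000	C	T	0.086	0.014	1.05e-09	0.025	0.014	0.085
rs6568479	6	107500000	A	G	0.086	0.014	8.91e-10	0.026	0.014	0.07
rs6915343	6	107500000	C	A	0.086	0.014	1.01e-09	0.024	0.014	0.086
rs6919118	6	107500000	T	C	0.086	0.014	1.06e-09	0.025	0.014	0.085
rs6942255	6	107600000	G	A	0.082	0.014	9.79e-09	0.037	0.014	0.01
rs7741724	6	107500000	G	A	0.086	0.014	1.05e-09	0.025	0.014	0.078
rs7741987	6	107500000	A	G	0.086	0.014	1.05e-09	0.025	0.014	0.085
rs7745311	6	107600000	T	C	0.081	0.014	1.23e-08	0.037	0.014	0.008
rs7749559	6	107500000	T	C	0.084	0.015	1.24e-08	0.03	0.015	0.055
rs7750154	6	107500000	T	G	0.086	0.014	1.14e-09	0.025	0.014	0.084
rs7754744	6	107600000	A	G	0.082	0.014	8.80e-09	0.037	0.014	0.01
rs9320207	6	107500000	T	C	0.086	0.014	1.11e-09	0.025	0.014	0.085
rs9372155	6	107500000	C	T	0.086	0.014	1.14e-09	0.025	0.014	0.085
rs9386627	6	107500000	T	C	0.086	0.014	1.01e-09	0.025	0.014	0.082
rs9386630	6	107600000	T	G	0.082	0.014	1.07e-08	0.037	0.014	0.009
rs9398123	6	107500000	A	C	0.086	0.014	1.13e-09	0.025	0.014	0.085
rs9398124	6	107500000	T	C	0.086	0.014	1.12e-09	0.025	0.014	0.085
rs9398125	6	107500000	A	C	0.086	0.014	1.05e-09	0.025	0.014	0.083
rs9398126	6	107500000	T	C	0.086	0.014	1.00e-09	0.025	0.014	0.082
rs9791276	6	107500000	C	T	0.086	0.014	1.15e-09	0.025	0.014	0.086
rs9791325	6	107500000	T	G	0.086	0.014	1.15e-09	0.025	0.014	0.086
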