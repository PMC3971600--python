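genome	butyrate_kinase	bcoat
Anaerostipes caccae DSM 14662	0	1
Anaerostipes sp. 3_2_56FAA	0	1
Butyrivibrio crossotus DSM 2876	1	0
Butyrivibrio proteoclasticus B316	1	0
Catonella morbi ATCC 51271	0	0
Cellulosilyticum lentocellum DSM 5427	0	0
Coprococcus comes ATCC 27758	1	0
Coprococcus eutactus ATCC 27759	1	0
Dorea formicigenerans ATCC 27755	0	0
Dorea longicatena DSM 13814	0	0
Lachnospiraceae bacterium 1_1_57FAA	0	0
Lachnospiraceae bacterium 1_4_56FAA	1	0
Lachnospiraceae bacterium 2_1_46FAA	0	0
Lachnospiraceae bacterium 2_1_58FAA	0	0
Lachnospiraceae bacterium 3_1_46FAA	0	0
Lachnospiraceae bacterium 3_1_57FAA_CT1	1	0
Lachnospiraceae bacterium 4_1_37FAA	0	0
Lachnospiraceae bacterium 5_1_57FAA	0	0
Lachnospiraceae bacterium 5_1_63FAA	0	1
Lachnospiraceae bacterium 6_1_63FAA	0	0
Lachnospiraceae bacterium 8_1_57FAA	0	0
Lachnospiraceae bacterium 9_1_43BFAA	0	0
Lachnospiraceae oral taxon 107 str. F0167	0	0
Marvinbryantia formatexigens DSM 14469	0	0
Oribacterium sinus F0268	0	0
Oribacterium sp. oral taxon 078 str. F0262	0	0
Oribacterium sp. oral taxon 108 str. F0425	0	0
Roseburia intestinalis L1-82	0	1
Roseburia inulinivorans DSM 16841	0	1
Shuttleworthia satelles DSM 14600	1	0
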