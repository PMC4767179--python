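strain	its1_species	its1_identity	its2_species	its2_identity	its2_cbc	its2_hcbc	rbcl_species	rbcl_identity
LBA#1	Desmodesmus armatus	95	Desmodesmus bicellularis	91	1	7	Scenedesmus quadricauda	90
LBA#2	Desmodesmus sp. MAT-2008c	100	Desmodesmus sp. MAT-2008c	100	0	0	Acutodesmus obliquus	93
LBA#3	Desmodesmus sp. MAT-2008c	100	Desmodesmus sp. MAT-2008c	100	0	0	Acutodesmus obliquus	90
LBA#4	Chlamydopodium starrii	70	Chlorococcum oleofaciens	91	1	2	Chlorococcum ellipsoideum	91
LBA#5	Desmodesmus sp. Tow 10/11 T-12W	79	Desmodesmus regularis	84	4	2	Desmodesmus santosii	93
LBA#6	Chlamydopodium starrii	70	Chlorococcum oleofaciens	94			Chlorococcum ellipsoideum	91
LBA#7	Desmodesmus sp. Tow 10/11 T-12W	79	Desmodesmus regularis	84	4	2	Desmodesmus santosii	93
LBA#8	Chlamydomonas sp. KU107	94	Chlamydomonas sp. KU107	87	0	1	Chlamydomonas oblonga	95
LBA#9	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#10	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#11	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#12	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1		
LBA#13	Coelastrella sp. shy-188	96	Scenedesmus rubescens	95	0	2	Scenedesmus quadricauda	90
LBA#14	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#15	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#16							Ecballocystopsis dichotomus	90
LBA#17	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#18	Chlamydopodium starrii	90	Chlamydopodium starrii	93	0	1	Chlorococcum ellipsoideum	92
LBA#19							Ecballocystopsis dichotomus	90
LBA#20	Coelastrum astroideum	76	Scenedesmus arcuatus	81	0	6	Hariotina reticulata	93
LBA#21	Coelastrella sp. shy-188	96	Scenedesmus rubescens	95	0	2	Desmodesmus costato-granulatus	94
LBA#22	Desmodesmus ultrasquamatus	100	Desmodesmus ultrasquamatus	99	0	0	Desmodesmus costato-granulatus	93
LBA#23	Desmodesmus ultrasquamatus	100	Desmodesmus ultrasquamatus	99	0	0	Desmodesmus costato-granulatus	94
LBA#24	Desmodesmus ultrasquamatus	94	Desmodesmus ultrasquamatus	94	0	3	Desmodesmus costato-granulatus	94
LBA#25	Desmodesmus ultrasquamatus	94	Desmodesmus ultrasquamatus	94	0	3	Desmodesmus costato-granulatus	94
LBA#26	Desmodesmus sp. MAT-2008c	100	Desmodesmus sp. MAT-2008c	100	0	0	Acutodesmus obliquus	92
LBA#27	Chlorella sorokiniana	100	Chlorella sorokiniana	100	0	0	Chlorella sorokiniana	99
LBA#28							Selenastrum sp. KMMCC 1456	94
LBA#29	Chlorella sp. MAT-2008a	92	Chlorella sp. MAT-2008a	91	0	2	Chlorella sp. IFRPD 1018	93
LBA#30	Desmodesmus sp. MAT-2008c	100	Desmodesmus sp. MAT-2008c	100	0	0	Acutodesmus obliquus	93
LBA#31	Chlorella sp. MAT-2008a	92	Chlorella sp. MAT-2008a	91	0	2	Chlorella sp. IFRPD 1018	93
LBA#32	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#33	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#34	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#35	Desmodesmus sp. GM4a	100	Desmodesmus sp. GM4a	99	0	1	Desmodesmus baconii	93
LBA#36	Desmodesmus sp. MAT-2008c	100	Desmodesmus sp. MAT-2008c	100	0	0	Acutodesmus obliquus	93
LBA#37	Chlamydomonas sp. YB3-2	90	Chlamydomonas applanata	92	1	2	Ascochloris multinucleata	94
LBA#38	Chlamydomonas sp. YB3-2	90	Chlamydomonas applanata	92	1	2	Ascochloris multinucleata	94
LBA#39	Chlorella sorokiniana KU207	100	Chlorella sorokiniana	100	0	0	Chlorella sorokiniana	99
LBA#40	Chlamydomonas zebra	79	Chlamydomonas sp. XJU-36	95	2	0	Chlamydomonas orbicularis	96
LBA#41	Chlamydomonas sp. KU107	94	Chlamydomonas sp. KU107	87	0	3	Chlamydomonas oblonga	95
LBA#42	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#43	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#44	Micractinium sp. CCAP 211/92	99	Micractinium sp. CCAP 211/92	100	0	0	Chlorella pyrenoidosa	99
LBA#45	Chlorococcum oleofaciens	82	Spongiochloris spongiosa	86			Protosiphon botryoides	92
LBA#46	Uronema sp. AF-2012	98	Uronema trentonense	100	0	0		
LBA#47	Tetracystis tetraspora	95	Dunaliella sp. SPMO 300-4	85	2	0	Nautococcus solutus	91
LBA#48							Gungnir sp. NIES-1851	93
LBA#49	Lobochlamys segnis	83	Chlamydomonas sp. CCAP 11/150	90	0	1	Asterococcus korschikoffii	90
LBA#50	Chlorella sp. KMMCC 1468	99	Chlorella sorokiniana	96	0	0	Chlorella sp. IFRPD 1014	99
LBA#51	Chlorococcum oleofaciens	74	Chlorococcum sp. CCAP 11/52	84	2	1	Chlamydopodium vacuolatum	95
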