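species
Acutodesmus obliquus
Ascochloris multinucleata
Asterococcus korschikoffii
Chlamydomonas applanata
Chlamydomonas oblonga
Chlamydomonas orbicularis
Chlamydomonas sp. CCAP 11/150
Chlamydomonas sp. KU107
Chlamydomonas sp. XJU-36
Chlamydomonas sp. YB3-2
Chlamydomonas zebra
Chlamydopodium starrii
Chlamydopodium vacuolatum
Chlorella sorokiniana
Chlorella sorokiniana KU207
Chlorella sp. IFRPD 1014
Chlorella sp. IFRPD 1018
Chlorella sp. KMMCC 1468
Chlorella sp. MAT-2008a
Chlorococcum ellipsoideum
Chlorococcum oleofaciens
Chlorococcum sp. CCAP 11/52
Coelastrella sp. shy-188
Coelastrum astroideum
Desmodesmus armatus
Desmodesmus baconii
Desmodesmus bicellularis
Desmodesmus costato-granulatus
Desmodesmus regularis
Desmodesmus santosii
Desmodesmus sp. GM4a
Desmodesmus sp. MAT-2008c
Desmodesmus sp. Tow 10/11 T-12W
Desmodesmus ultrasquamatus
Dunaliella sp. SPMO 300-4
Ecballocystopsis dichotomus
Gungnir sp. NIES-1851
Hariotina reticulata
Lobochlamys segnis
Micractinium sp. CCAP 211/92
Nautococcus solutus
Protosiphon botryoides
Scenedesmus arcuatus
Scenedesmus quadricauda
Scenedesmus rubescens
Selenastrum sp. KMMCC 1456
Spongiochloris spongiosa
Tetracystis tetraspora
Uronema sp. AF-2012
Uronema trentonense
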