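taxon,group,grids_s0,grids_s1,grids_s2,grids_s3,pct_s0,pct_s1,pct_s2,pct_s3
Hydracarina,Ara,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Dryopidae,COL,40351,28004,23111,19036,31.61,21.94,18.11,14.91
Dytiscidae,COL,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Elmidae,COL,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Gyrinidae,COL,33066,20042,15384,11853,25.91,15.70,12.05,9.29
Haliplidae,COL,77619,75282,73597,71340,60.81,58.98,57.66,55.89
Hydraenidae,COL,77025,70338,66878,62508,60.35,55.11,52.40,48.97
Hydrophilidae,COL,54433,43440,39382,34931,42.65,34.03,30.85,27.37
Scirtidae,COL,49017,35214,28280,21658,38.40,27.59,22.16,16.97
Atyidae,CRU,1,0,0,0,0.00,0.00,0.00,0.00
Gammaridae,CRU,3216,3538,3622,3668,2.52,2.77,2.84,2.87
Ostracoda,CRU,119666,120270,120465,120633,93.75,94.23,94.38,94.51
Athericidae,DIP,32439,20275,16184,12930,25.41,15.88,12.68,10.13
Ceratopogonidae,DIP,120338,120287,120280,120266,94.28,94.24,94.23,94.22
Chironomidae,DIP,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Culicidae,DIP,13734,6292,4059,2272,10.76,4.93,3.18,1.78
Dixidae,DIP,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Empididae,DIP,46540,35039,29992,25849,36.46,27.45,23.50,20.25
Limoniidae,DIP,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Psychodidae,DIP,30326,18997,15580,12487,23.76,14.88,12.21,9.78
Simuliidae,DIP,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Stratiomyidae,DIP,45549,33228,28680,24178,35.69,26.03,22.47,18.94
Tabanidae,DIP,117154,116879,116804,116720,91.78,91.57,91.51,91.44
Tipulidae,DIP,70774,61627,56347,50552,55.45,48.28,44.15,39.61
Baetidae,EPH,121302,121303,121303,121303,95.03,95.04,95.04,95.04
Caenidae,EPH,119612,120049,120189,120339,93.71,94.05,94.16,94.28
Ephemerellidae,EPH,95315,91614,89550,87519,74.67,71.78,70.16,68.57
Ephemeridae,EPH,17245,9533,6948,4850,13.51,7.47,5.44,3.80
Heptageniidae,EPH,47938,34783,29839,25012,37.56,27.25,23.38,19.60
Leptophlebiidae,EPH,110744,108926,108218,107687,86.76,85.34,84.78,84.37
Corixidae,HET,88830,92472,93988,95397,69.59,72.45,73.64,74.74
Gerridae,HET,120161,119919,119768,119667,94.14,93.95,93.83,93.75
Hydrometridae,HET,103470,100909,100116,99474,81.06,79.06,78.44,77.93
Naucoridae,HET,3179,3580,3913,4162,2.49,2.80,3.07,3.26
Nepidae,HET,1402,1296,1299,1196,1.10,1.02,1.02,0.94
Notonectidae,HET,113735,114775,115255,115692,89.11,89.92,90.30,90.64
Veliidae,HET,98865,93179,90841,88132,77.46,73.00,71.17,69.05
Erpobdellidae,HIR,1,0,0,0,0.00,0.00,0.00,0.00
Glossiphoniidae,HIR,1,0,0,0,0.00,0.00,0.00,0.00
Sialidae,NEU,155,21,0,0,0.12,0.02,0.00,0.00
Ancylidae,MOL,105267,107613,108442,109019,82.47,84.31,84.96,85.41
Hydrobiidae,MOL,30685,20574,16683,13559,24.04,16.12,13.07,10.62
Lymnaeidae,MOL,27028,15422,11330,7744,21.18,12.08,8.88,6.07
Physidae,MOL,1230,1404,1585,1699,0.96,1.10,1.24,1.33
Planorbidae,MOL,241,214,172,108,0.19,0.17,0.13,0.08
Sphaeriidae,MOL,31579,19764,15544,12256,24.74,15.48,12.18,9.60
Aeshnidae,ODO,42513,29837,24868,20206,33.31,23.38,19.48,15.83
Calopterygidae,ODO,21920,12624,9505,6816,17.17,9.89,7.45,5.34
Coenagrionidae,ODO,72397,80497,83324,85973,56.72,63.07,65.28,67.36
Cordulegasteridae,ODO,29496,17723,13729,10685,23.11,13.89,10.76,8.37
Gomphidae,ODO,56138,44792,39343,34141,43.98,35.09,30.82,26.75
Libellulidae,ODO,56642,66391,70934,75087,44.38,52.01,55.57,58.83
Leuctridae,PLE,112889,111732,110878,109827,88.44,87.54,86.87,86.04
Nemouridae,PLE,108002,106469,105996,105745,84.61,83.41,83.04,82.85
Perlidae,PLE,8112,4625,3766,3045,6.36,3.62,2.95,2.39
Perlodidae,PLE,101822,101119,101017,101031,79.77,79.22,79.14,79.15
Brachycentridae,TRI,817,585,495,410,0.64,0.46,0.39,0.32
Glossosomatidae,TRI,12561,6835,4753,2890,9.84,5.35,3.72,2.26
Hydropsychidae,TRI,92623,88136,86340,85030,72.57,69.05,67.64,66.62
Hydroptilidae,TRI,81858,75691,70895,65359,64.13,59.30,55.54,51.21
Leptoceridae,TRI,86805,80015,76040,71642,68.01,62.69,59.57,56.13
Limnephilidae,TRI,67538,58597,53984,49448,52.91,45.91,42.29,38.74
Philopotamidae,TRI,9783,7030,5980,4929,7.66,5.51,4.69,3.86
Polycentropodidae,TRI,52042,37873,31762,25820,40.77,29.67,24.88,20.23
Psychomyiidae,TRI,10820,6396,4563,3298,8.48,5.01,3.57,2.58
Rhyacophilidae,TRI,43324,29555,24577,20571,33.94,23.15,19.25,16.12
Sericostomatidae,TRI,20081,12477,9739,7401,15.73,9.78,7.63,5.80
Dugesiidae,Tur,9625,4770,2884,1463,7.54,3.74,2.26,1.15
Planariidae,Tur,1492,1013,859,753,1.17,0.79,0.67,0.59
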