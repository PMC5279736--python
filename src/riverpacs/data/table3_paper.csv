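taxon,group,ibmwp_score,dif_pct_s1,dif_pct_s2,dif_pct_s3,mean_alt_s0,alt_shift_s1,alt_shift_s2,alt_shift_s3,ap_printed
Gammaridae,CRU,6,10.01,12.62,14.05,81.44,28.57,37.03,40.18,4
Atyidae,CRU,6,-100.00,-100.00,-100.00,100.00,,,,4
Erpobdellidae,HIR,3,-100.00,-100.00,-100.00,100.00,,,,4
Glossiphoniidae,HIR,3,-100.00,-100.00,-100.00,100.00,,,,4
Planorbidae,MOL,3,-11.20,-28.63,-55.19,144.81,-14.44,-55.28,-115.18,4
Libellulidae,ODO,8,17.21,25.23,32.56,353.89,29.05,42.07,53.69,3
Coenagrionidae,ODO,6,11.19,15.09,18.75,390.85,26.16,34.16,41.93,2
Physidae,MOL,3,14.15,28.86,38.13,397.40,31.66,37.43,45.80,4
Corixidae,HET,3,4.10,5.81,7.39,416.86,10.65,15.12,19.30,2
Naucoridae,HET,3,12.61,23.09,30.92,460.21,36.92,54.49,67.42,4
Notonectidae,HET,3,0.91,1.34,1.72,477.00,1.45,1.65,2.01,1
Caenidae,EPH,4,0.37,0.48,0.61,489.26,1.96,2.63,3.38,1
Gerridae,HET,3,-0.20,-0.33,-0.41,491.75,-0.75,-1.31,-1.72,1
Ostracoda,CRU,3,0.50,0.67,0.81,495.78,1.46,1.89,2.32,1
Ancylidae,MOL,6,2.23,3.02,3.56,498.24,-1.14,-1.53,-1.57,1
Hydracarina,Ara,4,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Dytiscidae,COL,3,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Elmidae,COL,5,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Chironomidae,DIP,2,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Dixidae,DIP,4,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Limoniidae,DIP,4,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Simuliidae,DIP,5,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Baetidae,EPH,4,0.00,0.00,0.00,499.16,0.00,0.00,0.00,1
Ceratopogonidae,DIP,4,-0.04,-0.05,-0.06,502.79,0.17,0.20,0.24,1
Tabanidae,DIP,4,-0.23,-0.30,-0.37,504.68,2.07,2.68,3.42,1
Hydroptilidae,TRI,6,-7.53,-13.39,-20.16,508.37,-15.61,-22.85,-32.88,2
Nepidae,HET,3,-7.56,-7.35,-14.69,514.41,33.97,45.87,43.20,4
Leuctridae,PLE,10,-1.02,-1.78,-2.71,516.92,-1.63,-1.86,-1.93,1
Hydrometridae,HET,3,-2.48,-3.24,-3.86,517.77,-1.20,-3.28,-5.99,1
Leptophlebiidae,EPH,10,-1.64,-2.28,-2.76,525.82,-0.59,-1.47,-2.34,1
Nemouridae,PLE,7,-1.42,-1.86,-2.09,530.92,-1.37,-2.66,-3.76,1
Perlodidae,PLE,10,-0.69,-0.79,-0.78,535.40,-3.69,-5.98,-8.36,1
Ephemerellidae,EPH,7,-3.88,-6.05,-8.18,536.22,-7.54,-11.16,-14.05,1
Haliplidae,COL,4,-3.01,-5.18,-8.09,542.12,-15.24,-26.44,-40.19,2
Hydropsychidae,TRI,5,-4.84,-6.78,-8.20,542.52,7.67,10.93,12.91,1
Leptoceridae,TRI,10,-7.82,-12.40,-17.47,546.24,-16.55,-26.76,-39.90,2
Veliidae,HET,3,-5.75,-8.12,-10.86,551.69,-6.19,-12.91,-21.65,1
Hydraenidae,COL,5,-8.68,-13.17,-18.85,572.96,-3.29,-6.01,-12.10,2
Tipulidae,DIP,5,-12.92,-20.38,-28.57,590.21,-1.39,-4.27,-10.29,2
Hydrophilidae,COL,3,-20.20,-27.65,-35.83,633.36,17.33,17.75,12.74,3
Limnephilidae,TRI,7,-13.24,-20.07,-26.78,645.69,37.17,53.17,66.92,2
Gomphidae,ODO,8,-20.21,-29.92,-39.18,656.71,32.82,51.09,67.10,3
Polycentropodidae,TRI,7,-27.23,-38.97,-50.39,712.96,54.41,81.33,107.61,3
Stratiomyidae,DIP,4,-27.05,-37.03,-46.92,717.23,57.08,76.11,93.11,3
Aeshnidae,ODO,8,-29.82,-41.50,-52.47,726.98,50.93,67.13,80.65,3
Scirtidae,COL,3,-28.16,-42.31,-55.82,738.59,56.80,95.66,144.04,3
Rhyacophilidae,TRI,7,-31.78,-43.27,-52.52,741.93,48.50,67.44,81.98,3
Empididae,DIP,4,-24.71,-35.56,-44.46,745.71,51.08,74.77,95.78,3
Dryopidae,COL,5,-30.60,-42.73,-52.82,762.18,54.39,71.46,80.04,3
Hydrobiidae,MOL,3,-32.95,-45.63,-55.81,764.33,37.37,46.90,49.31,3
Heptageniidae,EPH,10,-27.44,-37.76,-47.82,774.34,74.38,107.69,139.67,3
Athericidae,DIP,10,-37.50,-50.11,-60.14,799.05,69.05,92.52,119.37,3
Lymnaeidae,MOL,3,-42.94,-58.08,-71.35,802.20,84.97,129.22,174.70,4
Psychomyiidae,TRI,8,-40.89,-57.83,-69.52,802.29,-68.04,-106.41,-155.38,4
Gyrinidae,COL,3,-39.39,-53.47,-64.15,805.56,79.81,111.37,137.59,3
Philopotamidae,TRI,8,-28.14,-38.87,-49.62,809.04,8.25,27.08,56.05,4
Sphaeriidae,MOL,3,-37.41,-50.78,-61.19,832.39,73.16,101.42,130.93,3
Cordulegasteridae,ODO,8,-39.91,-53.45,-63.77,835.03,83.43,114.16,137.42,4
Calopterygidae,ODO,8,-42.41,-56.64,-68.91,842.59,68.29,102.06,137.37,4
Psychodidae,DIP,4,-37.36,-48.62,-58.82,859.99,73.97,100.02,127.57,3
Ephemeridae,EPH,10,-44.72,-59.71,-71.88,919.81,71.48,106.73,140.44,4
Sericostomatidae,TRI,10,-37.87,-51.50,-63.14,929.36,61.85,88.15,111.01,4
Culicidae,DIP,2,-54.19,-70.45,-83.46,930.84,101.89,147.41,164.59,4
Dugesiidae,Tur,5,-50.44,-70.04,-84.80,938.03,45.85,31.25,-37.75,4
Perlidae,PLE,10,-42.99,-53.57,-62.46,982.89,11.08,17.96,23.65,4
Sialidae,NEU,4,-86.45,-100.00,-100.00,993.55,-55.45,,,4
Glossosomatidae,TRI,8,-45.59,-62.16,-76.99,997.88,86.77,133.63,174.16,4
Planariidae,Tur,5,-32.10,-42.43,-49.53,1199.73,81.22,117.38,143.30,4
Brachycentridae,TRI,10,-28.40,-39.41,-49.82,1333.90,85.75,124.48,162.92,4
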