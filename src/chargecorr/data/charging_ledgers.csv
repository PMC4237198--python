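guest,environment,scheme,box,Nw,L,raw,dG_pol,dG_sum,dG_hs,dG_excl,corrected
MAM,CAPO,LS,ss,471,2.46,-4.4,-71.2,-75.4,0.0,-0.2,-151.2
MAM,CAPO,LS,s,780,2.90,-12.4,-62.4,-76.3,0.0,-0.1,-151.2
MAM,CAPO,LS,m,1095,3.24,-17.6,-56.8,-76.9,0.0,-0.1,-151.4
MAM,CAPO,LS,l,1792,3.81,-24.7,-49.2,-77.1,0.0,-0.1,-151.1
MAM,CAPO,BM,m,1095,3.24,-8.5,-72.3,-68.9,0.0,-0.3,-150.0
MAM,CAPO,BM,l,1792,3.81,-9.7,-71.3,-67.8,0.0,-0.3,-149.1
MAM,CHB,LS,ss,469,2.46,-38.7,-70.5,-75.4,-0.7,-0.2,-185.5
MAM,CHB,LS,s,780,2.90,-47.3,-61.8,-76.3,-0.4,-0.1,-185.9
MAM,CHB,LS,m,1095,3.24,-53.2,-56.3,-77.1,-0.3,-0.1,-187.0
MAM,CHB,LS,l,1781,3.81,-59.7,-48.9,-77.3,-0.2,-0.1,-186.2
MAM,CHB,BM,m,1095,3.24,-44.1,-71.2,-69.0,-0.9,-0.3,-185.5
MAM,CHB,BM,l,1781,3.80,-44.3,-70.2,-68.0,-0.9,-0.3,-183.7
MAM,CPOS,LS,ss,473,2.46,115.7,-209.7,-75.4,155.8,-0.2,-13.8
MAM,CPOS,LS,s,780,2.90,111.2,-184.6,-76.3,133.3,-0.1,-16.5
MAM,CPOS,LS,m,1090,3.23,107.6,-168.6,-76.9,120.0,-0.1,-18.0
MAM,CPOS,LS,l,1772,3.80,102.8,-146.4,-77.1,102.6,-0.1,-18.2
MAM,CPOS,BM,m,1090,3.23,122.2,-212.8,-69.1,142.4,-0.3,-17.6
MAM,CPOS,BM,l,1772,3.80,119.7,-209.9,-68.2,142.4,-0.3,-16.3
MAM,CNEG,LS,ss,473,2.46,-234.2,69.9,-75.4,-157.9,-0.2,-397.8
MAM,CNEG,LS,s,780,2.90,-245.4,61.5,-76.3,-134.6,-0.1,-394.9
MAM,CNEG,LS,m,1095,3.25,-252.6,56.0,-76.5,-120.5,-0.1,-393.7
MAM,CNEG,LS,l,1785,3.81,-261.2,48.6,-77.2,-102.9,-0.1,-392.8
MAM,CNEG,BM,m,1095,3.25,-248.9,70.8,-68.3,-145.1,-0.3,-391.8
MAM,CNEG,BM,l,1785,3.81,-248.7,69.8,-67.7,-145.1,-0.3,-392.0
MAM,W,LS,ss,533,2.54,-172.6,-75.8,-77.8,0.0,-0.2,-326.4
MAM,W,LS,s,800,2.90,-181.8,-66.7,-78.3,0.0,-0.1,-326.9
MAM,W,LS,m,1091,3.21,-188.1,-60.4,-78.4,0.0,-0.1,-327.0
MAM,W,LS,l,1827,3.80,-197.8,-51.3,-79.2,0.0,-0.1,-328.4
MAM,W,BM,m,1091,3.21,-173.7,-77.4,-76.6,0.0,-0.3,-328.0
MAM,W,BM,l,1827,3.80,-175.5,-75.7,-79.2,0.0,-0.3,-330.7
ACE,CAPO,LS,ss,468,2.46,-74.5,-70.8,75.4,0.0,-0.3,-70.2
ACE,CAPO,LS,s,780,2.90,-84.5,-62.1,76.3,0.0,-0.2,-70.5
ACE,CAPO,LS,m,1095,3.24,-90.8,-56.5,76.8,0.0,-0.1,-70.6
ACE,CAPO,LS,l,1792,3.81,-99.1,-49.0,77.1,0.0,-0.1,-71.1
ACE,CAPO,BM,m,1095,3.24,-65.9,-71.7,68.4,0.0,-0.4,-69.6
ACE,CAPO,BM,l,1792,3.81,-66.2,-70.7,67.4,0.0,-0.4,-69.9
ACE,CHB,LS,ss,471,2.46,-117.8,-70.2,75.4,-0.2,-0.3,-113.1
ACE,CHB,LS,s,780,2.90,-128.0,-61.7,76.3,-0.1,-0.2,-113.7
ACE,CHB,LS,m,1090,3.24,-134.1,-56.3,76.9,-0.1,-0.1,-113.7
ACE,CHB,LS,l,1784,3.81,-142.7,-48.8,77.2,-0.1,-0.1,-114.5
ACE,CHB,BM,m,1090,3.24,-109.5,-71.0,68.5,-0.3,-0.3,-112.6
ACE,CHB,BM,l,1784,3.81,-110.0,-70.0,67.6,-0.3,-0.3,-113.0
ACE,CPOS,LS,ss,474,2.47,-288.7,70.0,75.5,-157.6,-0.3,-301.1
ACE,CPOS,LS,s,780,2.90,-301.9,61.6,76.3,-134.5,-0.2,-298.7
ACE,CPOS,LS,m,1095,3.24,-310.1,56.1,76.5,-120.5,-0.1,-298.1
ACE,CPOS,LS,l,1781,3.80,-319.8,48.8,77.3,-103.0,-0.1,-296.8
ACE,CPOS,BM,m,1095,3.24,-290.5,70.8,68.3,-144.8,-0.3,-296.5
ACE,CPOS,BM,l,1781,3.80,-289.3,69.8,67.9,-144.9,-0.3,-296.8
ACE,CNEG,LS,ss,479,2.47,37.5,-208.9,75.5,155.8,-0.3,59.5
ACE,CNEG,LS,s,780,2.90,30.2,-184.6,76.3,133.7,-0.2,55.4
ACE,CNEG,LS,m,1095,3.24,25.0,-168.2,76.7,120.0,-0.1,53.4
ACE,CNEG,LS,l,1788,3.81,18.0,-146.1,77.2,102.5,-0.1,51.5
ACE,CNEG,BM,m,1095,3.24,55.4,-212.9,68.4,143.2,-0.3,53.8
ACE,CNEG,BM,l,1788,3.81,53.3,-210.1,67.7,143.2,-0.3,53.8
ACE,W,LS,ss,526,2.53,-300.8,-76.0,77.6,0.0,-0.3,-299.5
ACE,W,LS,s,800,2.90,-310.6,-66.6,78.3,0.0,-0.2,-299.1
ACE,W,LS,m,1132,3.25,-318.6,-59.7,78.9,0.0,-0.1,-299.5
ACE,W,LS,l,1826,3.81,-327.0,-51.2,79.1,0.0,-0.1,-299.2
ACE,W,BM,m,1132,3.25,-299.8,-77.2,77.0,0.0,-0.3,-300.3
ACE,W,BM,l,1826,3.81,-301.5,-75.6,79.0,0.0,-0.3,-298.4
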