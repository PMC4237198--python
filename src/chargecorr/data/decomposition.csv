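guest,host,scheme,box,raw_solvent,raw_host,cor_solvent,cor_host
MAM,CAPO,LS,ss,-4.4,0.0,-151.2,0.0
MAM,CAPO,LS,s,-12.4,0.0,-151.2,0.0
MAM,CAPO,LS,m,-17.6,0.0,-151.4,0.0
MAM,CAPO,LS,l,-24.7,0.0,-151.1,0.0
MAM,CAPO,BM,m,-8.5,0.0,-150.0,0.0
MAM,CAPO,BM,l,-9.7,0.0,-149.1,0.0
MAM,CHB,LS,ss,-1.8,-36.9,-147.9,-37.6
MAM,CHB,LS,s,-9.9,-37.4,-148.1,-37.8
MAM,CHB,LS,m,-15.0,-38.2,-148.5,-38.5
MAM,CHB,LS,l,-21.9,-37.8,-148.2,-38.0
MAM,CHB,BM,m,-6.4,-37.7,-146.9,-38.6
MAM,CHB,BM,l,-7.4,-36.9,-145.9,-37.8
MAM,CPOS,LS,ss,-48.5,164.2,-333.8,320.0
MAM,CPOS,LS,s,-75.1,186.3,-336.1,319.6
MAM,CPOS,LS,m,-91.6,199.2,-337.2,319.2
MAM,CPOS,LS,l,-114.5,217.3,-338.1,319.9
MAM,CPOS,BM,m,-54.7,176.9,-336.9,319.3
MAM,CPOS,BM,l,-57.0,176.7,-335.4,319.1
MAM,CNEG,LS,ss,57.3,-291.5,51.6,-449.4
MAM,CNEG,LS,s,69.2,-314.6,54.3,-449.2
MAM,CNEG,LS,m,76.2,-328.8,55.6,-449.3
MAM,CNEG,LS,l,85.2,-346.4,56.5,-449.3
MAM,CNEG,BM,m,55.4,-304.3,57.6,-449.4
MAM,CNEG,BM,l,55.7,-304.4,57.5,-449.5
ACE,CAPO,LS,ss,-74.5,0.0,-70.2,0.0
ACE,CAPO,LS,s,-84.5,0.0,-70.5,0.0
ACE,CAPO,LS,m,-90.8,0.0,-70.6,0.0
ACE,CAPO,LS,l,-99.1,0.0,-71.1,0.0
ACE,CAPO,BM,m,-65.9,0.0,-69.6,0.0
ACE,CAPO,BM,l,-66.2,0.0,-69.9,0.0
ACE,CHB,LS,ss,-71.1,-46.7,-66.2,-46.9
ACE,CHB,LS,s,-81.1,-46.9,-66.7,-47.0
ACE,CHB,LS,m,-87.2,-46.9,-66.7,-47.0
ACE,CHB,LS,l,-95.4,-47.3,-67.1,-47.4
ACE,CHB,BM,m,-62.8,-46.7,-65.6,-47.0
ACE,CHB,BM,l,-63.1,-46.9,-65.8,-47.2
ACE,CPOS,LS,ss,-16.1,-272.6,129.1,-430.2
ACE,CPOS,LS,s,-6.4,-295.5,131.3,-430.0
ACE,CPOS,LS,m,-0.4,-309.7,132.1,-430.2
ACE,CPOS,LS,l,7.2,-327.0,133.2,-430.0
ACE,CPOS,BM,m,-5.2,-285.3,133.6,-430.1
ACE,CPOS,BM,l,-4.0,-285.3,133.4,-430.2
ACE,CNEG,LS,ss,-134.5,172.0,-268.2,327.8
ACE,CNEG,LS,s,-163.8,194.0,-272.3,327.7
ACE,CNEG,LS,m,-182.5,207.5,-274.1,327.5
ACE,CNEG,LS,l,-207.1,225.1,-276.1,327.6
ACE,CNEG,BM,m,-129.0,184.4,-273.8,327.6
ACE,CNEG,BM,l,-131.1,184.4,-273.8,327.6
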