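guest,host,scheme,water_box,host_box,ddG_raw
MAM,CAPO,LS,ss,l,147.9
MAM,CHB,LS,ss,l,112.9
MAM,CPOS,LS,ss,l,275.4
MAM,CNEG,LS,ss,l,-88.6
ACE,CAPO,LS,ss,l,201.7
ACE,CHB,LS,ss,l,158.1
ACE,CPOS,LS,ss,l,-19.0
ACE,CNEG,LS,ss,l,318.8
MAM,CAPO,LS,ss,ss,168.2
MAM,CHB,LS,ss,ss,133.9
MAM,CPOS,LS,ss,ss,288.3
MAM,CNEG,LS,ss,ss,-61.6
ACE,CAPO,LS,ss,ss,226.3
ACE,CHB,LS,ss,ss,183.0
ACE,CPOS,LS,ss,ss,12.1
ACE,CNEG,LS,ss,ss,338.3
MAM,CAPO,LS,s,s,169.4
MAM,CHB,LS,s,s,134.5
MAM,CPOS,LS,s,s,293.0
MAM,CNEG,LS,s,s,-63.6
ACE,CAPO,LS,s,s,226.1
ACE,CHB,LS,s,s,182.6
ACE,CPOS,LS,s,s,8.7
ACE,CNEG,LS,s,s,340.8
MAM,CAPO,LS,m,m,170.5
MAM,CHB,LS,m,m,134.9
MAM,CPOS,LS,m,m,295.7
MAM,CNEG,LS,m,m,-64.5
ACE,CAPO,LS,m,m,227.8
ACE,CHB,LS,m,m,184.5
ACE,CPOS,LS,m,m,8.5
ACE,CNEG,LS,m,m,343.6
MAM,CAPO,LS,l,l,173.1
MAM,CHB,LS,l,l,138.1
MAM,CPOS,LS,l,l,300.6
MAM,CNEG,LS,l,l,-63.4
ACE,CAPO,LS,l,l,227.9
ACE,CHB,LS,l,l,184.3
ACE,CPOS,LS,l,l,7.2
ACE,CNEG,LS,l,l,345.0
MAM,CAPO,BM,m,l,164.0
MAM,CHB,BM,m,l,129.4
MAM,CPOS,BM,m,l,293.4
MAM,CNEG,BM,m,l,-75.0
ACE,CAPO,BM,m,l,233.6
ACE,CHB,BM,m,l,189.8
ACE,CPOS,BM,m,l,10.5
ACE,CNEG,BM,m,l,353.1
MAM,CAPO,BM,m,m,165.2
MAM,CHB,BM,m,m,129.6
MAM,CPOS,BM,m,m,295.9
MAM,CNEG,BM,m,m,-75.2
ACE,CAPO,BM,m,m,233.9
ACE,CHB,BM,m,m,190.3
ACE,CPOS,BM,m,m,9.3
ACE,CNEG,BM,m,m,355.2
MAM,CAPO,BM,l,l,165.8
MAM,CHB,BM,l,l,131.2
MAM,CPOS,BM,l,l,295.2
MAM,CNEG,BM,l,l,-73.2
ACE,CAPO,BM,l,l,235.3
ACE,CHB,BM,l,l,191.5
ACE,CPOS,BM,l,l,12.2
ACE,CNEG,BM,l,l,354.8
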