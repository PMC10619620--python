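host,guest,HG,HW,GW,WW,total,dN_wat,dN_wat_footnote
CB7,1-AdOH,0.6,-0.7,-0.8,3.1,2.2,6.4,False
CB7,"4,9-DA(OH)2",0.0,0.0,-0.1,2.6,2.5,6.4,False
CB8,1-AdOH,0.2,-0.2,-0.5,2.7,2.2,9.2,True
CB8,"4,9-DA(OH)2",1.2,-1.2,-1.5,4.2,2.7,10.3,True
b-CD,1-AdOH,0.1,-0.4,-0.5,1.8,1.0,7.2,False
b-CD,"4,9-DA(OH)2",0.0,-1.0,-0.2,1.8,0.6,7.7,False
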