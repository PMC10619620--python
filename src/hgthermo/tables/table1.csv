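host,guest,dG_exp,dH_exp,mTdS_exp,dCp
CB7,1-AdOH,-14.2,-19.4,5.2,-102
CB7,4-DAOH,-9.5,-12.1,2.6,-66
CB7,"4,9-DA(OH)2",-9.6,-12.6,3.0,-135
CB7,FeCp2OH,-12.8,-21.0,8.2,-64
CB7,Nan,-8.9,-12.7,3.8,-144
CB7,L-Phe,-8.2,-9.5,1.3,-64
CB7,HexOH,-8.0,-9.6,1.6,-89
CB8,1-AdOH,-9.3,-8.1,-1.2,-83
CB8,4-DAOH,-9.1,-8.0,-1.1,-79
CB8,"4,9-DA(OH)2",-9.9,-7.7,-2.2,-103
CB8,"3,9-TA(OH)2",-9.5,-12.7,3.2,-97
CB8,FeCp2OH,-9.0,-13.1,4.1,-55
CB8,Nan,-9.5,-8.9,-0.6,-105
b-CD,1-AdOH,-6.5,-6.5,0.0,-95
b-CD,"4,9-DA(OH)2",-6.9,-8.9,2.0,-61
b-CD,FeCp2OH,-5.5,-7.7,2.2,-61
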