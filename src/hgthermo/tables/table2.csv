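host,guest,dG_exp,dG_calc,dH_exp,dH_calc,mTdS_exp,mTdS_calc
CB7,1-AdOH,-14.2,-23.1,-19.4,-25.9,5.2,2.8
CB7,"4,9-DA(OH)2",-9.6,-14.6,-12.6,-17.5,3.0,2.9
CB8,1-AdOH,-9.3,-15.2,-8.1,-10.0,-1.2,-5.2
CB8,"4,9-DA(OH)2",-9.9,-19.4,-7.7,-15.1,-2.2,-4.3
b-CD,1-AdOH,-6.5,-8.4,-6.5,-7.8,0.0,-0.6
b-CD,"4,9-DA(OH)2",-6.9,-9.8,-8.9,-11.2,2.0,1.4
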