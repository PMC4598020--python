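site,species,P_N,P_N_se,P_G,P_G_se,R,R_se,G,G_se,n
northern,P. astreoides,6.4,0.3,11.4,0.1,5.0,0.2,15.7,0.2,5
northern,S. cf. stellata,3.3,0.3,6.5,0.2,3.2,0.1,10.7,0.2,5
northern,M. harttii,1.8,0.4,4.7,0.1,2.9,0.2,10.1,0.3,5
southern,P. astreoides,6.6,0.6,12.3,0.2,5.7,0.1,16.1,0.3,5
southern,S. cf. stellata,5.4,0.2,8.4,0.2,3.0,0.1,14.3,0.3,5
southern,M. harttii,3.1,0.6,5.8,0.1,2.7,0.3,12.7,0.2,5
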