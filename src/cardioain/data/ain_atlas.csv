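label,hemisphere,family,x,y,z
Insula_L,L,insula,-35,7,3
Insula_R,R,insula,39,6,2
Cingulum_Ant_L,L,ACC,-4,35,14
Cingulum_Ant_R,R,ACC,8,37,16
Cingulum_Mid_L,L,MCC,-5,-15,42
Cingulum_Mid_R,R,MCC,8,-9,40
Cingulum_Post_L,L,PCC,-5,-43,25
Cingulum_Post_R,R,PCC,7,-42,22
Frontal_Med_Orb_L,L,OFCmed,-5,54,-7
Frontal_Med_Orb_R,R,OFCmed,8,52,-7
Frontal_Sup_Orb_L,L,OFCsup,-17,47,-13
Frontal_Sup_Orb_R,R,OFCsup,18,48,-14
Frontal_Mid_Orb_L,L,OFCmid,-31,50,-10
Frontal_Mid_Orb_R,R,OFCmid,33,53,-11
Frontal_Inf_Orb_L,L,OFCinf,-36,31,-12
Frontal_Inf_Orb_R,R,OFCinf,41,32,-12
Amygdala_L,L,amygdala,-23,-1,-17
Amygdala_R,R,amygdala,27,1,-18
Hippocampus_L,L,hippocampus,-25,-21,-10
Hippocampus_R,R,hippocampus,29,-20,-10
ParaHippocampal_L,L,parahippocampal,-21,-16,-21
ParaHippocampal_R,R,parahippocampal,25,-15,-20
Thalamus_L,L,thalamus,-11,-18,8
Thalamus_R,R,thalamus,13,-18,8
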