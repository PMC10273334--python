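specimen_id,taxon,source,endocast_volume_cm3,brain_volume_cm3,body_mass_g
NHMUK_PV_R_4769,Tomistoma dowsoni,this_study,23.41,8.19,168653.9
TMM_M6342,Tomistoma schlegelii,this_study,19.39,7.19,93619.6
FLMNH_UF_118998,Gavialis gangeticus,this_study,38.31,11.69,170000.0
Agaresuchus_SM2019,Agaresuchus fontisensis,serrano_martinez_2019,14.70,5.90,58107.02
Alligator_SM2019,Alligator mississippiensis,serrano_martinez_2019,18.72,7.01,104328.28
Caiman_SM2019,Caiman crocodilus,serrano_martinez_2019,4.94,3.71,5887.67
Crocodylus_niloticus_SM2019,Crocodylus niloticus,serrano_martinez_2019,24.76,8.56,151389.30
Lohuecosuchus_SM2019,Lohuecosuchus megadontos,serrano_martinez_2019,13.60,5.58,88719.46
Osteolaemus_SM2019,Osteolaemus tetraspis,serrano_martinez_2019,11.59,4.98,20228.39
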