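specimen_id,taxon,source,endocast_volume_mm3,optic_lobe_volume_mm3
NHMUK_PV_R_4769,Tomistoma dowsoni,this_study,23405.1,2868.1
TMM_M6342,Tomistoma schlegelii,this_study,19390.5,2105.7
FLMNH_UF_118998,Gavialis gangeticus,this_study,38309.9,6996.5
Agaresuchus_SM2019,Agaresuchus fontisensis,serrano_martinez_2019,14696.4,2263.6
Alligator_SM2019,Alligator mississippiensis,serrano_martinez_2019,18719.9,2467.9
Caiman_SM2019,Caiman crocodilus,serrano_martinez_2019,4941.7,936.5
Crocodylus_niloticus_SM2019,Crocodylus niloticus,serrano_martinez_2019,24764.8,3789.0
Lohuecosuchus_SM2019,Lohuecosuchus megadontos,serrano_martinez_2019,13604.5,1885.9
Osteolaemus_SM2019,Osteolaemus tetraspis,serrano_martinez_2019,11593.1,2577.4
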