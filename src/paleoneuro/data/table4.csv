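specimen_id,taxon,source,olfactory_bulb_diameter_mm,cerebral_hemisphere_diameter_mm
NHMUK_PV_R_4769,Tomistoma dowsoni,this_study,17.59,29.19
TMM_M6342,Tomistoma schlegelii,this_study,19.13,28.89
FLMNH_UF_118998,Gavialis gangeticus,this_study,16.65,33.29
Agaresuchus_SM2019,Agaresuchus fontisensis,serrano_martinez_2019,17.81,30.34
Alligator_SM2019,Alligator mississippiensis,serrano_martinez_2019,17.30,29.80
Caiman_SM2019,Caiman crocodilus,serrano_martinez_2019,10.92,19.62
Crocodylus_niloticus_SM2019,Crocodylus niloticus,serrano_martinez_2019,20.37,30.50
Lohuecosuchus_SM2019,Lohuecosuchus megadontos,serrano_martinez_2019,20.80,33.52
Osteolaemus_SM2019,Osteolaemus tetraspis,serrano_martinez_2019,15.43,24.90
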