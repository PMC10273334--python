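specimen_id,taxon,source,skull_width_at_cerebrum_mm,cephalic_flexure_deg,pontine_flexure_deg,endocast_length_mm,olfactory_tract_length_mm,cerebrum_width_mm,pituitary_width_mm,pituitary_height_mm,pituitary_length_mm,labyrinth_height_mm,labyrinth_width_mm,cochlear_duct_length_mm,asc_area_mm2,psc_area_mm2,lsc_area_mm2
NHMUK_PV_R_4769,Tomistoma dowsoni,this_study,109,143,149,146,66,30,9,9,17,19,15,11,21,10,?
TMM_M6342,Tomistoma schlegelii,this_study,68,134,134,97,47,27,5,8,14,18,17,10,17,5,4
FLMNH_UF_118998,Gavialis gangeticus,this_study,135,155,119,120,49,28,7,9,16,19,17,10,20,6,10
UMZC_R5792,Gavialis gangeticus,pierce_2017,168,150,154,146,55,32,6,9,11,21,21,9,36,15,22
MLP_602,Gavialis gangeticus,bona_2015,?,144,148,134,52,31,8,10,10,14,17,7,26,10,14
Agaresuchus_SM2019,Agaresuchus fontisensis,serrano_martinez_2019,106,149,149,107,43,20,7,11,6,?,?,?,?,?,?
Alligator_WR2008,Alligator mississippiensis,witmer_ridgely_2008,73,135,145,98,48,21,5,8,10,18,14,8,35,12,13
Arenysuchus_PP2015,Arenysuchus gascabadiolorum,puertolas_pascual_2015,70,154,152,54,20,18,4,5,7,?,?,?,?,?,?
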