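specimen_id,taxon,source,ecology,group,skull_rostrum_ratio,skull_width_ratio,skull_class
USNM_211233,Alligator mississippiensis,dufeau_witmer_2015,semi-aquatic,Alligatoridae,0.44,0.62,brevirostrine
FMNH_73711,Caiman crocodilus,brusatte_2016,semi-aquatic,Crocodylidae,0.64,0.31,mesorostrine
MLP_72_IV_7_1,Cricosaurus araucanensis,ristevski_2022,pelagic,Thalattosuchia,0.66,0.17,longirostrine
OUVC_10425,Crocodylus johnstoni,brusatte_2016,semi-aquatic,Crocodylidae,0.63,0.38,mesorostrine
NMB_AB50_0171,Crocodylus rhombifer,ristevski_2022,semi-aquatic,Crocodylidae,0.65,0.45,mesorostrine
FLMNH_UF_118998,Gavialis gangeticus,this_study,semi-aquatic,Gavialoidea,0.78,0.29,longirostrine
UMZC_R5792,Gavialis gangeticus,pierce_2017,semi-aquatic,Gavialoidea,0.78,0.29,longirostrine
MLP_68_IX_V_1,Gryposuchus neogaeus,bona_2015,semi-aquatic,Gavialoidea,0.78,0.28,longirostrine
QMF_548,Gunggamarandu maunala,ristevski_2022,semi-aquatic,Tomistominae,0.71,0.27,longirostrine
IVPP_V14010,Junggarsuchus sloani,ristevski_2022,terrestrial,Solidocrania,0.52,0.54,brevirostrine
BSPG_1984_I258,Macrospondylus bollensis,ristevski_2022,semi-aquatic,Thalattosuchia,?,0.36,longirostrine
TMM_M3529,Mecistops cataphractus,ristevski_2022,semi-aquatic,Crocodylidae,0.72,0.44,longirostrine
NHMUK_PV_OR_32617,Metriorhynchus brachyrhynchus,schwab_2020,pelagic,Thalattosuchia,0.4,0.19,mesorostrine
MLP_73_IV_15_9,Mourasuchus arendsi,bona_2013,semi-aquatic,Alligatoridae,0.69,0.62,brevirostrine
FMNH_98386,Osteolaemus tetraspis,ristevski_2022,semi-aquatic,Crocodylidae,0.64,0.39,mesorostrine
NHMUK_PV_OR_33095,Plagiophthalmosuchus gracilirostris,schwab_2020,pelagic,Thalattosuchia,?,?,longirostrine
BP_1_4770,Protosuchus haughtoni,ristevski_2022,terrestrial,Protosuchidae,0.43,0.49,brevirostrine
AMNH_FARB_33354,Rhabdognathus aslerensis,erb_turner_2021,pelagic,Dyrosauria,0.71,0.45,longirostrine
NHMUK_PV_R_4769,Tomistoma dowsoni,this_study,semi-aquatic,Gavialoidea,0.72,0.25,longirostrine
TMM_M6342,Tomistoma schlegelii,this_study,semi-aquatic,Tomistominae,0.74,0.22,longirostrine
USNM_211322,Tomistoma schlegelii,ristevski_2022,semi-aquatic,Tomistominae,0.74,0.22,longirostrine
QMF_16856,Trilophosuchus rackhami,ristevski_2022,terrestrial,Mekosuchinae,0.4,0.66,brevirostrine
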