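specimen_id,cerebrum_width_to_skull_width,cerebrum_width_to_endocast_length,olfactory_tract_to_endocast_length,pituitary_width_to_height,pituitary_width_to_length,pituitary_length_to_hindcast_length,labyrinth_width_to_height,cochlear_duct_to_labyrinth_height,asc_to_psc_area,asc_to_lsc_area,psc_to_lsc_area
NHMUK_PV_R_4769,0.27,0.21,0.45,1.00,0.53,0.21,0.79,0.58,2.10,?,?
TMM_M6342,0.39,0.28,0.48,0.63,0.36,0.28,0.94,0.56,3.40,4.25,1.25
FLMNH_UF_118998,0.21,0.23,0.41,0.78,0.44,0.23,0.89,0.53,3.33,2.00,0.60
UMZC_R5792,0.19,0.22,0.38,0.67,0.55,0.12,1.00,0.43,2.40,1.64,0.68
MLP_602,?,0.23,0.38,0.80,0.80,0.12,1.21,0.50,2.60,1.86,0.71
Agaresuchus_SM2019,0.18,0.18,0.40,0.63,1.16,0.09,?,?,?,?,?
Alligator_WR2008,0.28,0.21,0.48,0.63,0.50,0.20,0.78,0.44,2.91,2.69,0.92
Arenysuchus_PP2015,0.26,0.33,0.37,0.80,0.57,0.21,?,?,?,?,?
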