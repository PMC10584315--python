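symbol,definition,value,unit
T_base,Base temperature,10,degC
T_upper,Upper limit temperature,35,degC
K_cTr,Crop coefficient,1.15,
CC_0,Initial canopy cover,0.9,%
CGC,Canopy growth coefficient,0.966,%/d
CC_x,Maximum canopy cover,94,%
CDC,Canopy decay coefficient,0.798,%/GDD
WP_star,Standard water productivity,20,g/m2
Z_max,Maximum effective root depth,0.45,m
HI_0,Reference harvest index,55,%
p_exp_upper,Upper limit of the effect of water stress on canopy,0.26,
p_exp_lower,Lower limit of the effect of water stress on canopy,0.66,
p_sto_upper,Upper limit of the effect of water stress on stomatal conductance,0.65,
p_sen_upper,Upper limit of the effect of water stress on early canopy senescence,0.69,
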