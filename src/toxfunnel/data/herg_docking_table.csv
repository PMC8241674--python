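compound,role,lbe_mean_kcal,lbe_sd_kcal,ki_mean_uM,ki_sd_uM
deoxydihydro_artemisinin,derivative,-5.050,0.000,198.777,0.235
3_hydroxydeoxy_dihydroartemisinin,derivative,-5.053,0.006,197.417,0.556
3_desoxy_dihydroartemisinin,derivative,-5.050,0.000,200.210,0.113
dihydroartemisinin_furanoacetate,derivative,-4.893,0.006,258.980,1.825
deoxyartemisinin,derivative,-5.230,0.000,146.603,0.391
artemisinin_g,derivative,-5.200,0.000,155.018,0.295
artemisinin_b,derivative,-4.467,0.031,531.677,29.573
doxorubicin,positive_control,-5.160,0.066,166.230,17.840
dexrazoxane,negative_control,-4.570,0.000,449.210,1.417
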