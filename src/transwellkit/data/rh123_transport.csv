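arm,papp_apbl_1e7,papp_apbl_sd_1e7,papp_blap_1e7,papp_blap_sd_1e7,printed_ratio,printed_ratio_sd,fluorescence_mean,fluorescence_sd,donor_conc_uM,n
baseline,11.81,0.56,52.74,2.09,4.47,0.24,34.51,1.18,10,4
verapamil_100uM,5.36,0.41,8.51,1.43,1.58,0.208,153.64,3.28,10,4
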