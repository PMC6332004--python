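compound_id,name,papp_apbl_1e6,papp_apbl_sd_1e6,papp_blap_1e6,papp_blap_sd_1e6,printed_efflux_ratio,logd_ph74,teer_mean,teer_sd,donor_conc_uM,n
1,umbelliferone,35.86,2.28,32.79,1.25,0.91,1.44,1321,129,50,6
2,osthol,23.79,1.44,20.37,3.04,0.86,4.08,1548,104,50,6
3,scopoletin,37.10,1.97,27.38,3.51,0.96,1.65,1586,194,50,6
4,peucedanol,9.91,0.21,18.97,0.38,1.91,0.63,1595,93,50,6
5,ulopterol,22.36,4.02,26.66,2.94,1.19,1.09,1664,190,50,6
6,angepubebisin,20.85,1.32,18.73,1.02,0.90,3.40,1347,110,50,6
7,psoralen,27.34,2.35,26.75,2.75,0.98,2.08,1549,82,50,6
8,xanthotoxin,26.21,3.54,23.34,1.67,0.89,2.17,1298,161,50,6
9,bergapten,43.62,2.13,37.38,5.81,0.86,2.17,1595,173,50,6
10,isoimperatorin,7.29,0.17,3.73,0.33,0.51,3.7,1615,136,50,6
11,columbianadin,10.42,0.95,7.12,0.12,0.68,4.28,1429,152,50,6
12,columbianetin acetate,38.34,1.72,33.74,6.35,0.88,2.54,1463,119,50,6
caffeine,caffeine,43.58,4.86,,,,,1635,53,10,6
atenolol,atenolol,0.76,0.16,,,,,1573,91,200,6
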