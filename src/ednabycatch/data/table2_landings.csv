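landing_id,method,bycatch_tonnes,se_tonnes,fraction,n,replicates_per_sample
1,logbook,622.06,63.79,0.471,12,
1,logbook_corr,545.25,,0.400,,
1,fisheries_control,523.89,23.60,0.385,6,
1,third_party,472.29,57.56,0.348,15,
1,ship_pw,404.35,44.65,0.297,5,3
1,factory_pw,374.35,23.20,0.275,8,3
2,logbook,744.88,114.25,0.492,18,
2,third_party,676.86,76.76,0.447,15,
2,factory_pw,513.99,26.87,0.339,10,3
3,logbook,558.86,208.11,0.388,6,
3,third_party,306.45,117.65,0.213,15,
3,ship_pw,529.79,58.69,0.368,8,3
3,factory_pw,237.66,42.5,0.165,8,3
4,logbook,546.89,133.26,0.441,10,
4,third_party,604.85,88.17,0.488,15,
4,ship_pw,761.96,109.78,0.614,6,3
4,factory_pw,215.41,30.62,0.174,8,3
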