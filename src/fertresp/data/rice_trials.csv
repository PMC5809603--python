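trial_id,site,crop,nutrient,rate_kg_hm2,yield_kg_hm2,yield_sd_kg_hm2
R1,Datian county,rice,N,0,5051,123
R1,Datian county,rice,N,37.5,5801,102
R1,Datian county,rice,N,75.0,6483,121
R1,Datian county,rice,N,112.5,6834,68
R1,Datian county,rice,N,150.0,7001,173
R1,Datian county,rice,N,187.5,6900,252
R1,Datian county,rice,N,225.0,6675,93
R1,Datian county,rice,N,262.5,6600,33
R4,Nan'an city,rice,P2O5,0,6809,286
R4,Nan'an city,rice,P2O5,22.5,7274,191
R4,Nan'an city,rice,P2O5,45.0,7490,180
R4,Nan'an city,rice,P2O5,67.5,7616,219
R4,Nan'an city,rice,P2O5,90.0,7577,344
R4,Nan'an city,rice,P2O5,112.5,7449,260
R4,Nan'an city,rice,P2O5,135.0,7236,180
R4,Nan'an city,rice,P2O5,157.5,6953,125
R7,Datian county,rice,K2O,0,7670,87
R7,Datian county,rice,K2O,30,8570,321
R7,Datian county,rice,K2O,60,9215,379
R7,Datian county,rice,K2O,90,9485,115
R7,Datian county,rice,K2O,120,9225,189
R7,Datian county,rice,K2O,150,8763,76
R7,Datian county,rice,K2O,180,8411,100
R7,Datian county,rice,K2O,210,7880,275
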