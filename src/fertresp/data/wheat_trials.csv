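trial_id,site,crop,nutrient,rate_kg_hm2,yield_kg_hm2,yield_sd_kg_hm2
W1,northern China,wheat,N,0,4133,
W1,northern China,wheat,N,45,5693,
W1,northern China,wheat,N,90,6458,
W1,northern China,wheat,N,135,7350,
W1,northern China,wheat,N,180,7178,
W1,northern China,wheat,N,225,6480,
W2,northern China,wheat,N,0,4313,
W2,northern China,wheat,N,45,4950,
W2,northern China,wheat,N,90,5063,
W2,northern China,wheat,N,135,4875,
W2,northern China,wheat,N,180,4688,
W3,northern China,wheat,N,0,2325,
W3,northern China,wheat,N,60,2700,
W3,northern China,wheat,N,120,3720,
W3,northern China,wheat,N,180,4260,
W3,northern China,wheat,N,240,4530,
W3,northern China,wheat,N,300,4343,
W4,northern China,wheat,urea,0,4080,
W4,northern China,wheat,urea,150,4785,
W4,northern China,wheat,urea,300,5355,
W4,northern China,wheat,urea,450,5783,
W4,northern China,wheat,urea,600,6165,
W4,northern China,wheat,urea,750,5895,
W5,northern China,wheat,N,0,2177,
W5,northern China,wheat,N,33.75,3413,
W5,northern China,wheat,N,67.5,4112,
W5,northern China,wheat,N,101.25,4514,
W5,northern China,wheat,N,135,4716,
W6,northern China,wheat,N,0,3995,
W6,northern China,wheat,N,33.75,4355,
W6,northern China,wheat,N,67.5,4602,
W6,northern China,wheat,N,101.25,4658,
W6,northern China,wheat,N,135,4703,
W7,northern China,wheat,N,0,2453,
W7,northern China,wheat,N,33.75,3075,
W7,northern China,wheat,N,67.5,3585,
W7,northern China,wheat,N,101.25,3656,
W7,northern China,wheat,N,135,3615,
W8,northern China,wheat,P2O5,0,2355,
W8,northern China,wheat,P2O5,37.5,3345,
W8,northern China,wheat,P2O5,75,4425,
W8,northern China,wheat,P2O5,112.5,5078,
W8,northern China,wheat,P2O5,150,5153,
W8,northern China,wheat,P2O5,187.5,4275,
W9,northern China,wheat,CS,0,480,
W9,northern China,wheat,CS,300,1208,
W9,northern China,wheat,CS,450,1455,
W9,northern China,wheat,CS,600,1733,
W9,northern China,wheat,CS,750,1995,
W9,northern China,wheat,CS,900,2160,
W9,northern China,wheat,CS,1125,2325,
W9,northern China,wheat,CS,1500,2355,
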