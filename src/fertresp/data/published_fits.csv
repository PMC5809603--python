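trial_id,crop,nutrient,n,A,c_e3,s0,f_nsfm,stars_nsfm,r2_nsfm,s_nsfm,b0,b1,b2,f_qpfm,stars_qpfm,r2_qpfm,s_qpfm
R1,rice,N,8,47.596,3.740,105.120,255.6,2,0.990,77.5,5087.6,22.273,-0.065,126.7,2,0.981,109.5
R2,rice,N,8,75.323,5.517,40.359,12.8,1,0.837,577.1,3086.6,44.886,-0.145,46.4,2,0.949,323.1
R3,rice,N,8,70.609,5.699,86.106,253.5,2,0.990,53.5,6154.7,27.199,-0.140,60.4,2,0.960,107.9
R4,rice,P2O5,8,63.739,5.607,106.790,1189.7,2,0.998,15.9,6858.5,18.775,-0.117,138.8,2,0.982,46.1
R5,rice,P2O5,8,67.972,5.189,112.790,23.8,2,0.905,127.7,7715.3,21.763,-0.124,21.7,2,0.897,133.1
R6,rice,P2O5,8,103.370,7.362,71.182,64.9,2,0.963,121.9,7587.4,29.559,-0.197,14.7,2,0.855,241.0
R7,rice,K2O,8,90.851,5.824,83.871,159.7,2,0.985,30.3,7788.7,29.707,-0.143,38.8,2,0.940,189.9
R8,rice,K2O,8,57.217,4.921,104.670,17.0,2,0.872,179.8,6096.2,18.697,-0.083,9.6,1,0.793,228.3
R9,rice,N,6,67.582,4.192,126.720,26.3,2,0.946,197.6,8624.6,22.802,-0.087,374.5,2,0.996,53.7
R10,rice,N,6,77.037,5.988,63.948,16.1,1,0.915,302.6,4988.8,33.911,-0.140,255.5,2,0.994,79.2
R11,rice,N,5,51.525,4.995,93.094,34.7,1,0.972,119.4,4825.1,21.924,-0.095,31.8,1,0.969,124.6
R12,rice,N,5,97.207,4.710,81.760,69.4,1,0.986,214.2,8097.9,42.347,-0.1427,14.8,0,0.937,452.0
R13,rice,P2O5,6,65.931,4.634,155.330,126.3,2,0.988,26.6,10252.0,15.854,-0.124,280.5,2,0.995,17.9
R14,rice,K2O,7,32.950,4.185,178.880,19.3,2,0.906,60.0,5920.3,8.1339,-0.043,11.0,1,0.846,76.9
R15,rice,K2O,7,46.920,3.887,164.070,30.2,2,0.938,82.1,7731.3,13.863,-0.066,20.2,2,0.910,98.8
R16,rice,K2O,6,77.715,4.429,109.860,272.3,2,0.995,68.6,8640.9,29.051,-0.111,32.7,2,0.956,194.2
R17,rice,K2O,5,39.449,4.173,136.380,145.7,2,0.993,35.4,5394.9,13.953,-0.063,337.2,2,0.997,23.3
R18,rice,K2O,4,74.698,4.297,135.560,396.2,1,0.999,39.8,10165.0,22.271,-0.098,15.5,0,0.938,198.2
W1,wheat,N,6,69.533,4.788,58.298,39.6,2,0.964,294.4,4099.6,40.684,-0.1326,112.5,2,0.987,174.7
W2,wheat,N,5,41.601,5.185,104.044,44.9,1,0.978,61.3,4363.9,13.881,-0.0688,11.5,0,0.920,117.6
W3,wheat,N,6,21.740,2.181,99.585,27.2,1,0.948,273.4,2149.0,16.325,-0.0288,35.1,2,0.959,242.0
W4,wheat,urea,6,21.548,1.864,187.080,66.5,2,0.978,150.5,4034.5,12.928,-0.0211,101.8,2,0.986,122.1
W5,wheat,N,5,55.004,5.301,39.774,2101.8,2,0.999,31.7,2212.3,38.324,-0.1482,361.1,2,0.997,76.4
W6,wheat,N,5,28.639,3.821,139.480,279.4,2,0.996,24.8,4001.0,12.052,-0.0516,170.7,2,0.994,31.7
W7,wheat,N,5,41.662,5.907,58.364,109.3,2,0.991,69.7,2443.7,23.521,-0.1105,167.1,2,0.994,56.4
W8,wheat,P2O5,6,64.806,6.027,33.830,17.7,1,0.922,388.8,2190.3,43.746,-0.1696,46.9,2,0.969,245.1
W9,wheat,CS,8,27.635,4.508,16.238,446.7,2,0.994,56.9,464.3,22.879,-0.0683,1582.8,2,0.998,30.3
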