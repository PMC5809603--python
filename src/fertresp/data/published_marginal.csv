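trial_id,site,nutrient,n,A,c_e3,s0,f_exp,r2_exp,s_exp,a,b,f_lin,r2_lin,s_lin
R1,Datian county,N,7,52.81,3.134,131.020,26.64,0.930,2.994,23.966,-0.1204,40.28,0.890,3.765
R4,Nan'an city,P2O5,7,74.23,4.887,120.610,299.54,0.993,1.048,22.229,-0.2368,119.55,0.960,2.579
R7,Datian county,K2O,7,102.40,4.864,99.362,41.38,0.954,4.503,34.429,-0.2786,40.07,0.889,6.891
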