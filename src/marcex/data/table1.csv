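temperature_C,concentration_pct,TPC_mean,TPC_sd,TPC_note,TFC_mean,TFC_sd,TFC_note,TC_mean,TC_sd,TC_note,TAC_mean,TAC_sd,TAC_note
30,0,3.41,0.21,c,1.83,0.03,b,0.27,0.02,c,0.02,0.01,a
30,40,4.78,0.18,d,3.04,0.12,c,0.47,0.02,d,0.35,0.01,c
30,60,7.51,0.25,f,4.89,0.09,e,0.84,0.03,g,0.67,0.01,f
30,80,5.76,0.18,e,4.31,0.10,e,0.74,0.05,"f,g",0.45,0.01,d
30,96,1.37,0.11,a,0.84,0.03,a,0.11,0.01,a,0.23,0.01,b
45,0,4.30,0.14,d,2.50,0.03,"b,c",0.35,0.04,"c,d",0.03,0.01,a
45,40,5.77,0.22,e,3.85,0.11,d,0.57,0.04,e,0.56,0.01,e
45,60,9.52,0.24,h,6.87,0.07,h,1.11,0.07,"i,j",0.79,0.01,g
45,80,7.14,0.13,f,5.43,0.05,f,0.95,0.04,h,0.62,0.01,f
45,96,1.73,0.11,a,0.94,0.04,a,0.14,0.02,"a,b",0.29,0.01,"b,c"
65,0,5.35,0.18,e,3.32,0.04,"c,d",0.53,0.02,e,0.05,0.01,a
65,40,8.69,0.17,g,5.98,0.08,g,1.16,0.04,"i,j",0.71,0.01,"f,g"
65,60,11.02,0.02,i,7.76,0.14,i,1.37,0.01,k,0.97,0.02,h
65,80,9.40,0.10,h,7.38,0.15,h,1.24,0.04,"j,k",0.79,0.01,g
65,96,2.39,0.10,b,1.48,0.04,a,0.18,0.01,b,0.38,0.01,c
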