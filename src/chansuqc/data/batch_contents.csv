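batch,origin,GB,GB_sd,TBG,TBG_sd,BFL,BFL_sd,CFL,CFL_sd,BL,BL_sd,CBG,CBG_sd,RBG,RBG_sd
AH 1,Anhui,10.99,0.26,10.33,0.16,19.11,0.14,19.72,0.35,27.23,0.20,56.35,0.62,25.50,0.21
AH 2,Anhui,12.80,0.46,8.14,0.14,18.89,0.25,17.92,0.45,23.27,0.27,54.10,0.67,28.90,0.25
AH 3,Anhui,11.48,0.21,9.53,0.04,19.07,0.20,18.93,0.04,25.64,0.14,55.44,0.45,26.99,0.24
AH 4,Anhui,11.56,0.26,9.22,0.08,18.99,0.03,18.78,0.07,24.28,1.25,55.47,0.47,27.29,0.41
HN 1,Henan,9.51,0.48,17.05,0.69,19.33,0.51,31.13,0.83,17.39,0.72,35.17,0.74,14.78,0.99
HN 2,Henan,10.48,0.53,15.16,0.70,19.57,0.96,27.54,0.85,18.77,0.71,37.31,1.84,12.97,0.90
HN 3,Henan,9.56,0.38,16.26,0.78,18.88,0.78,30.28,1.42,18.04,0.70,40.78,0.56,14.17,0.31
HN 4,Henan,9.72,0.57,15.74,0.38,18.47,0.84,30.57,0.46,17.99,0.72,39.35,1.80,15.07,0.61
JX 1,Jiangxi,6.24,0.37,6.35,0.36,25.19,0.86,26.27,0.78,20.64,0.47,32.23,0.55,23.72,0.49
JX 2,Jiangxi,6.26,0.18,6.81,0.33,24.14,1.02,26.02,0.59,18.94,1.07,32.32,1.52,23.09,1.19
JX 3,Jiangxi,8.12,0.09,8.46,0.26,27.23,0.27,29.74,0.22,18.53,0.98,28.99,0.49,17.38,1.19
JX 4,Jiangxi,7.17,0.10,7.94,0.14,25.29,0.77,29.54,0.48,18.87,0.14,30.84,0.36,18.62,0.26
SC 1,Sichuan,7.21,0.20,25.56,0.65,11.11,0.30,26.25,0.74,12.71,0.43,14.64,0.42,2.92,0.18
SC 2,Sichuan,5.89,0.36,21.97,0.28,19.00,0.23,30.56,0.39,15.43,0.06,16.22,0.20,6.71,0.16
SC 3,Sichuan,6.69,0.43,24.57,0.51,18.05,0.48,31.35,0.56,16.36,0.39,16.06,0.37,2.91,0.19
SC 4,Sichuan,6.58,0.29,24.23,0.38,17.74,0.25,31.39,0.66,16.13,0.27,15.81,0.06,2.90,0.13
ZJ 1,Zhejiang,5.34,0.11,11.86,0.28,19.84,0.48,22.08,0.84,18.68,0.58,30.02,0.72,23.92,0.46
ZJ 2,Zhejiang,5.10,0.14,11.41,0.26,19.17,0.48,21.73,0.50,17.97,0.41,29.17,0.77,23.49,0.47
ZJ 3,Zhejiang,4.28,0.09,9.03,0.20,16.45,0.19,19.08,0.68,18.07,0.15,29.56,0.38,26.98,0.19
ZJ 4,Zhejiang,4.54,0.13,9.65,0.27,17.33,0.25,19.67,1.07,18.91,0.28,30.99,0.40,28.50,0.43
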