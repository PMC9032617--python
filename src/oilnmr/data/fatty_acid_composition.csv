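row,AO-1,AO-2,AO-3,AO-4,SO,CO,RO
oil_type,Avocado Oil,Avocado Oil,Avocado Oil,Avocado Oil,Soybean Oil,Corn Oil,Rapeseed Oil
origin,France,France,New Zealand,Mexico,China,China,China
viscosity_mPa_s,61.56,61.50,61.22,60.12,48.20,50.96,56.56
C14:0,0.03,0.04,0.04,0.04,0.07,0.04,0.06
C16:0,11.84,10.66,11.47,12.76,10.66,11.21,4.67
C16:1,1.69,1.82,1.93,2.53,0.07,0.09,0.22
C18:0,2.44,2.31,2.33,2.25,4.19,2.06,1.85
C18:1n9c,69.20,70.91,71.03,64.49,24.09,28.19,58.14
C18:2n6c,13.24,12.76,11.77,16.25,53.39,56.84,20.24
C20:0,0.35,0.32,0.34,0.32,0.37,0.34,0.62
C18:3n6,ND,ND,ND,ND,0.05,0.04,0.59
C20:1,0.27,0.26,0.27,0.26,0.20,0.25,ND
C18:3n3,0.65,0.52,0.59,0.93,6.37,0.58,7.78
C20:2,ND,ND,ND,ND,ND,ND,0.12
C22:0,0.22,0.28,0.18,0.17,0.40,0.22,0.35
C20:3n3,ND,ND,ND,ND,ND,ND,5.09
C20:5n3,0.09,0.12,0.08,ND,0.13,0.14,ND
C24:1n9,ND,ND,ND,ND,ND,ND,0.28
SFA_printed,14.87,13.62,14.36,15.54,15.69,13.87,7.55
MUFA_printed,71.16,72.99,73.22,67.28,24.36,24.36,58.65
PUFA_printed,13.97,13.39,12.43,17.18,59.95,57.60,33.81
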