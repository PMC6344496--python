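name,species,value_unit,age_unit,alpha0_star,alphar_star,betar_star,td_years,tau_published,peak_moore_published,peak_imap1_published
100 m,human,m.s-1,years,34.26,21.40,2.19,124.13,5.80,25.88,24.99
400 m,human,m.s-1,years,67.64,25.51,2.79,109.54,4.29,25.46,22.70
800 m,human,m.s-1,years,25.29,16.92,2.18,110.01,6.50,25.74,25.40
3000 m,human,m.s-1,years,62.50,22.00,1.45,114.20,5.19,23.53,28.24
5000 m,human,m.s-1,years,45.24,19.25,2.20,109.51,5.69,25.65,28.95
10000 m,human,m.s-1,years,54.46,20.96,3.24,104.27,4.98,25.74,30.15
Marathon,human,m.s-1,years,34.32,16.00,2.27,106.39,6.65,27.82,26.94
Shotput,human,kg.m,years,223.84,20.28,3.01e-4,96.73,4.77,24.42,23.88
Weightlifting,human,kg,years,1011.39,25.70,3.74e-4,95.96,3.73,24.72,31.39
Chess,human,score,years,32.31,23.61,5.10,127.54,5.40,31.39,30.76
Facial recognition,human,proportion,years,22.37,25.09,2.36,185.00,7.37,29.61,30.06
Greyhound,greyhound,m.s-1,months,77.83,39.96,5.64,11.37,0.28,23.31,22.18
Mouse males,mouse,km.week-1,weeks,402.31,159.20,1.91,2.55,1.60e-2,0.14,0.11
Mouse females,mouse,km.week-1,weeks,108.53,83.74,0.97,2.53,3.02e-2,0.15,0.15
Mouse lemur males,mouse lemur,N,weeks,0.66,0.39,2.03,13.31,33.88,1.53,3.59
Mouse lemur females,mouse lemur,N,weeks,5.01,25.80,5.57,11.84,0.46,4.87e-2,2.06
Thoroughbred,thoroughbred,m.s-1,months,1125.04,46.33,9.16,18.21,0.39,5.25,4.58
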