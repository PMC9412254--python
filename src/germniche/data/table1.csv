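population,storage_month,stage,Tl50,sigma_Tl,Th50,sigma_Th,theta_sub50,sigma_sub,theta_sup50,sigma_sup,R2
Arak,0,D,6.6,7.2,19.3,11.8,29.3,18.3,20,5,0.93
Arak,0,M,6.6,4,23,9.31,26.9,7,18,5,0.91
Arak,1,AR1,6.6,2,26,6.5,26.8,7,17,5,0.98
Arak,2,AR2,6.6,2,32,4.5,17,6.9,16,5,0.98
Arak,5,AR5,6.6,2,35,2,15,4.4,16,4,0.97
Bajestan,0,D,6.3,4,15,10,26,6,28,4,0.93
Bajestan,0,M,6.3,4,22,7,24,6,28,4,0.97
Bajestan,1,AR1,6.3,3,25,6,23,6,25,3,0.89
Bajestan,2,AR2,6.3,2,29,5,15,5,20,3,0.86
Bajestan,5,AR5,6.3,2,32,2.7,15,5,20,2,0.95
Eshkazer,0,D,9,7,17.5,10,30,10,30,20,0.92
Eshkazer,0,M,9,6,19.5,8,30,10,30,7,0.91
Eshkazer,1,AR1,9,6,23.3,5,27,9,20,5,0.99
Eshkazer,2,AR2,9,3,25.62,3.5,22,6,20,4,0.99
Eshkazer,5,AR5,9,2.4,30,1.09,22,5,12,4,0.82
Gardmiran,0,D,5.8,8,17.5,22,20,8,40,12,0.96
Gardmiran,0,M,5.8,6.5,20,14,22,7,20,8,0.98
Gardmiran,1,AR1,5.8,5,22.5,9.36,15,6,18,4,0.92
Gardmiran,2,AR2,5.8,4,27,7.5,15,5,19,3,0.88
Gardmiran,5,AR5,5.8,2.9,30.5,4.8,10,2,15,2,0.95
Khaf,0,D,5.5,7,19.5,16,31,7,22,8,0.94
Khaf,0,M,5.5,5.9,22.9,7.5,30,4,22,8,0.99
Khaf,1,AR1,5.5,4,24,6,25,3,20,8,0.87
Khaf,2,AR2,5.5,3.5,29,3.8,19,2,18,8,0.98
Khaf,5,AR5,5.5,2.5,33,2,10,1.6,15,7,0.98
Razan,0,D,4,4,17,11,31,8.4,20,5,0.84
Razan,0,M,4,3,23,9.5,23,8,20,5,0.89
Razan,1,AR1,4,2.8,27,7,26.9,4.4,16,4,0.92
Razan,2,AR2,4,3,30,3.5,18.8,3.6,16,4,0.96
Razan,5,AR5,4,3,32,2,17,2,15,4,0.95
Semirom,0,D,3,4,22,8,32.6,7.1,20,5,0.89
Semirom,0,M,3,3,25,7,23,6,16,5,0.91
Semirom,1,AR1,3,3,31.8,5.5,16.6,4,16,4,0.88
Semirom,2,AR2,3,3,34,4,16.1,2,13,4,0.96
Semirom,5,AR5,3,3,35.5,1,12.9,0.8,10,3,0.98
Tafresh,0,D,4.8,8,19.6,10,30,8,20,5,0.80
Tafresh,0,M,4.8,3,22,8.5,23.8,7.8,16,4,0.89
Tafresh,1,AR1,4.8,3,25,7,18.4,7.2,16,4,0.93
Tafresh,2,AR2,4.8,2.5,29,5,15.7,6,15,4,0.96
Tafresh,5,AR5,4.8,2.5,33,5,14.9,4,14,4,0.96
Zabol,0,D,4.2,3,22,8,29.8,9.1,16,6,0.84
Zabol,0,M,4.2,1.5,25,6.3,24.3,6.71,15,6,0.94
Zabol,1,AR1,4.2,1.5,28,3.8,19.4,6.2,14,5,0.98
Zabol,2,AR2,4.2,1.5,30,2.5,15.1,4.8,12,5,0.95
Zabol,5,AR5,4.2,1,33,1,13.3,4,12,4,0.97
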