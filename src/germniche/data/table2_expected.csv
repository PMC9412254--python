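population,a,b,se_b,rwtn,p_value,r2,significant
Arak,24.29,0.003274,0.0009173,305.5,0.0703,0.86,no
Bajestan,23.14,0.002679,0.0006391,373.3,0.0525,0.89,no
Eshkazer,20.65,0.002748,0.0004617,363.9,0.0271,0.94,yes
Gardmiran,20.86,0.002877,0.0006115,347.6,0.0423,0.91,yes
Khaf,23.05,0.002897,0.0005693,345.2,0.0365,0.92,yes
Razan,24.71,0.002282,0.0007523,438.3,0.0937,0.82,no
Semirom,23.49,0.002450,0.001203,408.1,0.1785,0.81,no
Tafresh,22.96,0.002976,0.0005546,336.0,0.0330,0.93,yes
Zabol,26.00,0.002083,0.0004150,480.0,0.0375,0.92,yes
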