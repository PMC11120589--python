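arm,day,acidity,acidity_sd,phenols,phenols_sd,flavonoids,flavonoids_sd,betaine,betaine_sd,DPPH,DPPH_sd,ABTS,ABTS_sd
OD,0,1.30,0.25,1016.05,21.50,238.80,2.99,3175.46,21.36,1.56,0.13,0.49,0.01
ODC,0,1.06,0.07,1063.14,24.73,257.43,0.32,3343.13,25.58,1.37,0.05,0.21,0.00
OD,7,1.29,0.12,678.02,101.88,127.87,12.54,3081.34,73.88,2.17,0.01,0.58,0.06
ODC,7,0.99,0.01,920.26,23.50,221.73,8.00,3324.35,18.89,1.40,0.01,0.20,0.00
OD,14,0.85,0.03,468.28,12.09,88.43,3.65,2365.16,76.41,1.89,0.02,0.70,0.01
ODC,14,1.03,0.07,682.43,35.32,172.34,5.41,2625.28,91.13,1.07,0.05,0.44,0.00
OD,21,0.98,0.04,468.06,45.91,93.64,6.15,2872.90,61.83,2.13,0.17,0.45,0.04
ODC,21,0.93,0.08,864.56,15.50,146.36,3.24,2666.85,115.39,1.21,0.02,0.53,0.00
OD,28,0.85,0.11,458.09,7.97,63.37,0.93,2785.48,63.7,2.22,0.00,0.51,0.03
ODC,28,1.09,0.03,571.29,14.24,105.38,0.72,3082.87,56.24,1.29,0.03,0.23,0.01
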