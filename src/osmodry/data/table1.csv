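run,T,Conc,t,DMC,DMC_sd,WL,WL_sd,SG,SG_sd,Mg,Mg_sd,K,K_sd,Na,Na_sd,Ca,Ca_sd,DPPH,DPPH_sd,ABTS,ABTS_sd,flavonoids,flavonoids_sd,phenols,phenols_sd,acidity,acidity_sd,betaine,betaine_sd
1,20,60,3,26.737,0.134,0.536,0.006,0.005,0.000,375.44,0.37,10564.15,22.48,3798.08,19.10,595.18,3.52,4.51,0.01,1.92,0.12,135.50,5.47,450.38,68.26,1.52,0.23,1446.72,15.32
2,60,60,3,35.614,0.270,0.606,0.006,0.032,0.002,202.82,0.19,9050.28,7474.60,4007.28,22.75,1080.12,9.00,4.79,0.01,1.26,0.04,113.83,13.35,459.41,65.74,1.12,0.002,2475.85,9.38
3,20,80,3,29.572,0.178,0.571,0.005,0.009,0.000,354.46,0.74,11477.97,41.83,4178.06,15.76,689.61,8.58,6.63,0.01,1.98,0.01,106.98,0.63,343.57,9.46,1.39,0.01,1713.08,40.62
4,60,80,3,43.583,0.085,0.679,0.006,0.032,0.000,344.59,0.27,17968.71,113.41,5893.59,29.05,1324.41,10.99,4.23,0.02,0.91,0.06,119.17,2.18,488.18,10.22,1.15,0.14,2975.39,514.49
5,20,70,1,16.574,0.129,0.333,0.000,0.011,0.000,147.66,0.17,7861.18,52.01,3048.38,25.06,380.86,1.29,8.34,0.02,3.14,0.24,123.32,7.38,301.56,30.59,1.42,0.18,1111.45,61.40
6,60,70,1,26.790,0.183,0.508,0.003,0.016,0.000,328.24,0.69,10540.82,48.81,3737.85,23.29,609.54,7.36,5.44,0.02,1.44,0.08,112.84,2.61,405.61,6.20,1.34,0.001,1861.46,28.84
7,20,70,5,36.969,0.260,0.355,0.008,0.025,0.000,349.60,0.79,11961.57,3.68,4674.94,40.07,683.11,4.16,5.79,0.01,1.61,0.23,85.88,3.29,311.83,4.74,1.07,0.01,1976.45,15.57
8,60,70,5,50.149,0.626,0.708,0.004,0.050,0.000,158.18,0.11,15268.18,82.90,4729.92,29.07,1706.96,7.75,2.84,0.01,0.80,0.08,145.39,2.15,646.45,14.07,1.06,0.003,3828.18,30.16
9,40,60,1,22.921,0.053,0.449,0.001,0.009,0.000,319.23,1.25,8383.86,65.78,3037.02,20.93,424.39,5.17,5.72,0.01,1.99,0.89,142.77,5.13,468.44,6.94,1.39,0.07,1264.90,28.85
10,40,80,1,23.273,0.211,0.479,0.001,0.002,0.000,307.67,0.35,9657.91,68.56,3462.99,11.45,572.99,3.53,6.14,0.01,2.09,0.57,139.37,2.84,457.81,11.45,1.41,0.14,1484.54,16.16
11,40,60,5,38.287,0.226,0.633,0.005,0.036,0.000,377.15,1.19,16112.23,115.48,5339.88,31.25,991.61,10.36,4.78,0.01,1.30,0.02,102.53,0.83,455.47,9.26,1.21,0.08,2386.31,3.67
12,40,80,5,47.999,0.500,0.710,0.002,0.038,0.000,504.62,0.72,18174.63,160.90,7038.92,38.62,1182.05,9.28,4.16,0.01,1.43,0.06,93.36,1.95,400.25,47.17,1.32,0.00,3140.25,24.36
13,40,70,3,31.357,1.462,0.584,0.017,0.015,0.005,350.30,42.53,13083.26,560.93,4497.41,487.14,794.38,66.07,4.75,0.42,1.13,0.05,101.40,12.03,429.71,52.07,1.27,0.09,2312.04,42.95
14,40,70,3,31.087,1.526,0.583,0.018,0.015,0.005,349.73,41.21,13106.91,556.89,4504.91,476.96,794.58,65.25,4.74,0.41,1.11,0.04,102.07,11.77,482.18,84.29,1.34,0.35,2220.13,38.11
15,40,70,3,31.188,1.694,0.586,0.015,0.015,0.005,349.05,41.91,13003.68,487.00,4497.81,514.57,800.30,63.66,4.77,0.42,1.13,0.05,101.03,11.59,428.64,54.17,1.26,0.09,2170.54,54.22
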