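solvent,region,exposure,hblt_ps,hblt_ci_ps,D_1e5cm2s,D_ci_1e5cm2s,res_ps,res_ci_ps
water,alpha1,Ext,22.6,0.4,1.668,0.029,45.7,0.7
water,alpha2,Int-Ext,54.5,5.3,1.116,0.016,56.2,1.4
water,alpha3,Int-Ext,63.2,10.3,0.986,0.021,52.6,1.2
water,alpha4,Int,478,96,0.172,0.006,75.8,4.3
water,alpha5,Ext,25.3,3.9,1.384,0.044,42.5,0.6
water,alpha6,Int,459,110,0.586,0.054,63.2,1.6
water,alpha7,Int-Ext,20.6,2.0,1.258,0.097,46.1,1.6
water,alpha8,Ext,25.1,0.5,1.228,0.034,41.9,0.8
water,alpha9,Int-Ext,36.8,2.9,1.059,0.022,59.5,1.2
water,alpha10,Ext,43.3,2.3,1.454,0.009,44.3,0.3
n-butanol,alpha1,Ext,721,17,0.417,0.006,29.3,1.1
n-butanol,alpha2,Int-Ext,1202,241,0.271,0.004,23.3,1.7
n-butanol,alpha3,Int-Ext,792,78,0.279,0.003,25.1,1.0
n-butanol,alpha4,Int,1652,218,0.167,0.002,26.3,1.1
n-butanol,alpha5,Ext,422,34,0.368,0.004,35.8,1.1
n-butanol,alpha6,Int,,,0.266,0.005,31.1,1.2
n-butanol,alpha7,Int-Ext,884,42,0.338,0.004,28.7,1.4
n-butanol,alpha8,Ext,334,13,0.369,0.004,38.7,0.6
n-butanol,alpha9,Int-Ext,1063,113,0.254,0.011,20.0,0.3
n-butanol,alpha10,Ext,746,51,0.446,0.002,34.3,0.7
tert-butanol,alpha1,Ext,748,29,0.223,0.005,22.3,1.5
tert-butanol,alpha2,Int-Ext,660,49,0.192,0.007,25.0,3.6
tert-butanol,alpha3,Int-Ext,705,32,0.151,0.007,29.8,3.2
tert-butanol,alpha4,Int,,,0.099,0.010,45.4,1.8
tert-butanol,alpha5,Ext,270,65,0.180,0.003,27.2,2.5
tert-butanol,alpha6,Int,,,0.136,0.005,34.6,1.6
tert-butanol,alpha7,Int-Ext,177,36,0.136,0.006,33.6,4.8
tert-butanol,alpha8,Ext,1475,218,0.186,0.006,26.8,1.6
tert-butanol,alpha9,Int-Ext,734,39,0.123,0.004,36.3,4.1
tert-butanol,alpha10,Ext,1342,182,0.194,0.005,23.4,0.7
acetonitrile,alpha1,Ext,37.7,0.8,3.23,0.05,20.3,0.5
acetonitrile,alpha2,Int-Ext,19.5,0.3,2.32,0.07,33.6,0.6
acetonitrile,alpha3,Int-Ext,73.6,1.3,1.88,0.06,32.0,0.9
acetonitrile,alpha4,Int,,,1.68,0.07,37.2,1.0
acetonitrile,alpha5,Ext,210,47,3.01,0.05,29.8,0.6
acetonitrile,alpha6,Int,418,107,1.47,0.08,39.2,1.0
acetonitrile,alpha7,Int-Ext,36.8,0.6,2.79,0.06,32.5,1.0
acetonitrile,alpha8,Ext,,,3.04,0.07,29.6,0.4
acetonitrile,alpha9,Int-Ext,216,19,1.47,0.06,37.5,0.4
acetonitrile,alpha10,Ext,63.6,0.4,3.08,0.03,25.0,0.2
cyclohexane,alpha1,Ext,,,0.76,0.02,24.1,1.0
cyclohexane,alpha2,Int-Ext,,,0.67,0.02,29.4,0.9
cyclohexane,alpha3,Int-Ext,,,0.67,0.02,28.5,0.9
cyclohexane,alpha4,Int,,,0.64,0.02,38.6,0.9
cyclohexane,alpha5,Ext,,,0.95,0.02,20.8,1.0
cyclohexane,alpha6,Int,,,0.65,0.02,39.2,1.2
cyclohexane,alpha7,Int-Ext,,,0.74,0.01,24.1,0.6
cyclohexane,alpha8,Ext,,,0.78,0.02,23.8,0.3
cyclohexane,alpha9,Int-Ext,,,0.64,0.01,32.9,0.5
cyclohexane,alpha10,Ext,,,1.04,0.01,15.8,0.4
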