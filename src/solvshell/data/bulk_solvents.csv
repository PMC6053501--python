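solvent,eta_exp_mPas,D_exp_1e5cm2s,D_model_1e5cm2s,T_K
water,0.89,2.3,2.49,300
n-butanol,2.95,0.46,0.46,300
tert-butanol,3.35,0.30,0.29,301
acetonitrile,0.39,4.04,4.62,300
cyclohexane,0.98,1.47,1.05,300
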