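# Default combining coefficients of the three-step affinity model,
# ln K_D = b0 + b1*slide + b2*recognition + b3*bend  (ln-nM).
# These are starting values; calibrate_model refits them against observed
# K_D data (e.g. the packaged marker tables' printed K_D columns).
[model]
window_len = 15
b0 = 3.0
b1 = 0.5
b2 = -0.35
b3 = -0.5
residual_se = 0.3
pwm_pseudocount = 0.5
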