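spiked_mg_ml,tlc_mean,tlc_sd,tlc_recovery_mean,tlc_recovery_sd,imagej_mean,imagej_sd,imagej_recovery_mean,imagej_recovery_sd
4.0,4.00,0.07,100.08,1.83,3.98,0.02,99.48,0.55
3.6,3.60,0.10,100.16,2.96,3.54,0.08,98.56,2.26
3.0,2.89,0.12,96.61,3.71,3.00,0.07,100.13,2.45
2.4,2.39,0.07,99.85,0.40,2.37,0.04,98.75,1.81
2.0,2.02,0.07,101.17,3.66,2.05,0.07,102.44,3.62
1.0,1.03,0.07,102.67,6.93,0.98,0.05,98.37,4.76
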