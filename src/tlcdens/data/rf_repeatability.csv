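method,rf_mean,rf_sd,n
tlc_analyzer,0.604,0.017,18
imagej,0.605,0.005,18
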