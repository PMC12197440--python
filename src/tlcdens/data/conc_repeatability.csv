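method,level_mg_ml,mean_mg_ml,sd_mg_ml,n,printed_cv_percent
tlc_analyzer,4,4.00,0.07,6,1.8
tlc_analyzer,2,2.02,0.07,6,3.6
tlc_analyzer,1,1.03,0.07,6,6.7
imagej,4,3.98,0.02,6,0.5
imagej,2,2.05,0.07,6,3.5
imagej,1,0.98,0.05,6,4.8
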