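name,slope,intercept,linear_low_mg_ml,linear_high_mg_ml,lod_mg_ml,loq_mg_ml
imagej,10701,7502,0.5,4,1.45,4.41
tlc_analyzer_app,2404.70,9006.9,0.5,4,,
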