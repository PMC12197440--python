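method,cv_4mg,cv_2mg,cv_1mg,printed_average
tlc_analyzer,2.7,2.9,2.7,2.8
imagej,1.0,0.3,0.4,0.9
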