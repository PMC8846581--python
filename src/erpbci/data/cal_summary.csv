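test,n,pre_mean,pre_sd,post_mean,post_sd
cal_quantitative,10,28.90,11.10,34.30,11.45
cal_qualitative,10,76.90,25.45,84.40,24.48
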