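test,n,pre_mean,pre_sd,post_mean,post_sd
token,10,58.90,13.25,63.30,11.40
repetition,10,56.90,8.33,60.70,9.31
written_language,10,55.40,7.46,62.00,10.87
naming,10,56.50,8.28,67.50,13.48
comprehension,10,59.10,8.13,64.80,13.26
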