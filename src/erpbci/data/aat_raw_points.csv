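patient_id,chronic,pre,post,followup
1,321,318,374,374
2,490,495,517,
3,,471,523,518
4,470,457,503,475
5,448,467,519,508
6,430,448,494,473
7,446,468,492,504
8,473,466,498,503
9,243,245,276,291
10,181,198,240,254
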