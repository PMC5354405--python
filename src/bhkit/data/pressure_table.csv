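power_W,p_pos_MPa,p_pos_sd,p_neg_MPa,p_neg_sd
500,65.97,4.42,10.98,0.45
550,70.20,4.81,10.65,0.86
600,72.65,4.53,10.98,0.76
650,76.26,5.67,12.16,0.70
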