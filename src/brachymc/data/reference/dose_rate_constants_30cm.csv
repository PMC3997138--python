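medium,lambda_cGy_h_U,rel_unc
water,1.115,0.009
cortical_bone,1.097,0.009
inflated_lung,0.984,0.009
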