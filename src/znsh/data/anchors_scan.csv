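r_angstrom,e_s0_kcalmol,e_s1_kcalmol
3.302,34.4,73.0
2.103,44.0,45.6
1.517,18.9,52.0
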