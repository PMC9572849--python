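parameter,group1_mean,group2_mean,pct_diff_g2_vs_g1,pct_diff_s910_vs_s12_group1,pct_diff_s910_vs_s12_group2
EMGMAVback_right,0.022175,0.03393,53.00936,-9.24482,-7.92041
EMGMAVback_left,0.006357,0.032487,411.0173,-21.2933,-11.0977
EMGMAVchest_right,0.015085,0.018502,22.65795,-36.619,10.87285
EMGMAVchest_left,0.008021,0.018606,131.9509,24.61576,-10.82
EMGMAVarm_right,0.029902,0.042155,40.9753,-9.45086,-16.501
EMGMAVarm_left,0.029903,0.042155,40.9739,-9.45083,-16.5009
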