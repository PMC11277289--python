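parameter,M1,M2
sf_center_mu,5.0196,3.0521
sf_spread_sigma,0.9413,1.0300
ori_center_alpha,109.3960,23.9108
ori_spread_kappa,0.8362,0.1552
size_slope_m,0.3674,6.3396
size_midpoint_sigma0,1.2904,0.3190
con_slope_k,1.4808,1.1180
con_midpoint_c0,22.8935,32.1019
hue_center_r_rad,5.9789,6.2326
hue_spread_r_kappa,1.9068,4.2599
hue_center_c_rad,3.0042,3.7618
hue_spread_c_kappa,2.5095,1.8884
hue_gain_ac,0.4335,0.4030
hue_size_slope_m,1.6175,0.9333
hue_size_midpoint_sigma0,1.2120,0.2257
sat_slope_l,3.2922,4.2867
sat_midpoint_s0,0.7477,0.6463
val_slope_g,0.0807,0.00027
val_intercept_o,0.3472,0.4753
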