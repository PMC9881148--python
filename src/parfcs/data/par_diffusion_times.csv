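n_units,mass_kda,tau_calc_us,tau_exp_wt_us,tau_exp_hb_us,h_wt_reported,h_hb_reported
13,7.1,180,227,,5.1,
14,7.6,185,,247,,6.3
20,10.8,208,300,276,8.1,6.2
30,16.5,238,355,292,9,4.7
40,21.7,262,405,312,10,4.1
50,27.1,282,431,335,9.7,4.1
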