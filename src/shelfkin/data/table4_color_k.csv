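order,packaging,temperature_c,k,r_squared,note
zero,al_bag_n2,4,0.027,0.708,
zero,al_bag_air,4,0.050,0.810,
zero,clear_plastic,4,0.058,0.747,
zero,al_bag_n2,25,0.076,0.682,
zero,al_bag_air,25,0.86,0.900,scale_anomaly
zero,clear_plastic,25,0.097,0.868,
zero,al_bag_n2,35,0.15,0.908,
zero,al_bag_air,35,0.32,0.899,
zero,clear_plastic,35,0.19,0.678,
zero,al_bag_n2,45,0.24,0.999,
zero,al_bag_air,45,0.50,0.799,
zero,clear_plastic,45,0.50,0.824,
first,al_bag_n2,4,0.005,0.808,
first,al_bag_air,4,0.009,0.844,
first,clear_plastic,4,0.012,0.716,
first,al_bag_n2,25,0.002,0.922,conflicts_conclusions
first,al_bag_air,25,0.016,0.928,
first,clear_plastic,25,0.028,0.873,
first,al_bag_n2,35,0.032,0.950,
first,al_bag_air,35,0.080,0.919,
first,clear_plastic,35,0.075,0.972,
first,al_bag_n2,45,0.047,0.991,
first,al_bag_air,45,0.11,0.818,
first,clear_plastic,45,0.11,0.859,
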