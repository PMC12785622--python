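order,packaging,temperature_c,k,r_squared,note
zero,al_bag_n2,4,0.45,0.864,
zero,al_bag_air,4,0.43,0.782,
zero,clear_plastic,4,0.46,0.878,
zero,al_bag_n2,25,0.37,0.529,
zero,al_bag_air,25,0.43,0.831,
zero,clear_plastic,25,0.34,0.482,
zero,al_bag_n2,35,1.0,0.764,scale_anomaly
zero,al_bag_air,35,0.79,0.813,
zero,clear_plastic,35,0.69,0.525,
zero,al_bag_n2,45,0.81,0.452,
zero,al_bag_air,45,0.72,0.444,
zero,clear_plastic,45,0.87,0.648,
first,al_bag_n2,4,0.013,0.868,
first,al_bag_air,4,0.017,0.982,
first,clear_plastic,4,0.015,0.939,
first,al_bag_n2,25,0.017,0.768,
first,al_bag_air,25,0.018,0.946,
first,clear_plastic,25,0.019,0.904,
first,al_bag_n2,35,0.045,0.980,
first,al_bag_air,35,0.032,0.976,
first,clear_plastic,35,0.033,0.835,
first,al_bag_n2,45,0.049,0.972,
first,al_bag_air,45,0.042,0.955,
first,clear_plastic,45,0.035,0.755,
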