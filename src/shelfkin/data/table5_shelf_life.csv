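packaging,temperature_c,actual_weeks,actual_bound,predicted_weeks
al_bag_n2,4,24,greater_than,58
al_bag_n2,25,15,exact,14
al_bag_n2,35,12,exact,7
al_bag_n2,45,3,exact,4
al_bag_air,4,24,greater_than,23
al_bag_air,25,15,exact,14
al_bag_air,35,3,less_than,3
al_bag_air,45,3,less_than,2
clear_plastic,4,21,exact,19
clear_plastic,25,9,exact,8
clear_plastic,35,3,less_than,3
clear_plastic,45,3,less_than,2
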