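attribute,packaging,temperature_c,time_weeks,value,sd,n,qualifier,terminated
tbc,al_bag_n2,4,0,0.25,,,lt,
tbc,al_bag_n2,4,4,0.25,,,lt,
tbc,al_bag_n2,4,8,0.25,,,lt,
tbc,al_bag_n2,4,12,0.25,,,lt,
tbc,al_bag_n2,4,16,0.25,,,lt,
tbc,al_bag_n2,4,20,0.25,,,lt,
tbc,al_bag_n2,4,24,65,2,,,
tbc,al_bag_n2,25,0,0.25,,,lt,
tbc,al_bag_n2,25,4,0.25,,,lt,
tbc,al_bag_n2,25,8,0.25,,,lt,
tbc,al_bag_n2,25,12,0.25,,,lt,
tbc,al_bag_n2,25,16,0.25,,,lt,
tbc,al_bag_n2,25,20,0.25,,,lt,
tbc,al_bag_n2,25,24,65,8,,,
tbc,al_bag_n2,35,0,0.25,,,lt,
tbc,al_bag_n2,35,4,0.25,,,lt,
tbc,al_bag_n2,35,8,0.25,,,lt,
tbc,al_bag_n2,35,12,0.25,,,lt,
tbc,al_bag_n2,35,16,0.25,,,lt,1
tbc,al_bag_n2,45,0,0.25,,,lt,
tbc,al_bag_n2,45,4,0.25,,,lt,
tbc,al_bag_n2,45,8,0.25,,,lt,
tbc,al_bag_n2,45,12,0.25,,,lt,
tbc,al_bag_n2,45,16,0.25,,,lt,1
tbc,al_bag_air,4,0,0.25,,,lt,
tbc,al_bag_air,4,4,0.25,,,lt,
tbc,al_bag_air,4,8,0.25,,,lt,
tbc,al_bag_air,4,12,0.25,,,lt,
tbc,al_bag_air,4,16,55,4,,,
tbc,al_bag_air,4,20,55,2,,,
tbc,al_bag_air,4,24,75,11,,,
tbc,al_bag_air,25,0,0.25,,,lt,
tbc,al_bag_air,25,4,0.25,,,lt,
tbc,al_bag_air,25,8,0.25,,,lt,
tbc,al_bag_air,25,12,0.25,,,lt,
tbc,al_bag_air,25,16,25,3,,,
tbc,al_bag_air,25,20,60,4,,,
tbc,al_bag_air,25,24,85,9,,,
tbc,al_bag_air,35,0,0.25,,,lt,
tbc,al_bag_air,35,4,0.25,,,lt,
tbc,al_bag_air,35,8,0.25,,,lt,
tbc,al_bag_air,35,12,0.25,,,lt,
tbc,al_bag_air,35,16,20,2,,,1
tbc,al_bag_air,45,0,0.25,,,lt,
tbc,al_bag_air,45,4,0.25,,,lt,
tbc,al_bag_air,45,8,0.25,,,lt,
tbc,al_bag_air,45,12,0.25,,,lt,
tbc,al_bag_air,45,16,20,4,,,1
tbc,clear_plastic,4,0,0.25,,,lt,
tbc,clear_plastic,4,4,0.25,,,lt,
tbc,clear_plastic,4,8,0.25,,,lt,
tbc,clear_plastic,4,12,40,4,,,
tbc,clear_plastic,4,16,30,5,,,
tbc,clear_plastic,4,20,45,3,,,
tbc,clear_plastic,4,24,50,5,,,
tbc,clear_plastic,25,0,0.25,,,lt,
tbc,clear_plastic,25,4,0.25,,,lt,
tbc,clear_plastic,25,8,0.25,,,lt,
tbc,clear_plastic,25,12,40,6,,,
tbc,clear_plastic,25,16,20,4,,,
tbc,clear_plastic,25,20,30,2,,,
tbc,clear_plastic,25,24,55,5,,,
tbc,clear_plastic,35,0,0.25,,,lt,
tbc,clear_plastic,35,4,0.25,,,lt,
tbc,clear_plastic,35,8,0.25,,,lt,
tbc,clear_plastic,35,12,0.25,,,lt,
tbc,clear_plastic,35,16,45,6,,,1
tbc,clear_plastic,45,0,0.25,,,lt,
tbc,clear_plastic,45,4,0.25,,,lt,
tbc,clear_plastic,45,8,0.25,,,lt,
tbc,clear_plastic,45,12,0.25,,,lt,
tbc,clear_plastic,45,16,50,10,,,1
ymc,al_bag_n2,4,0,0.25,,,lt,
ymc,al_bag_n2,4,4,0.25,,,lt,
ymc,al_bag_n2,4,8,0.25,,,lt,
ymc,al_bag_n2,4,12,0.25,,,lt,
ymc,al_bag_n2,4,16,0.25,,,lt,
ymc,al_bag_n2,4,20,0.25,,,lt,
ymc,al_bag_n2,4,24,0.25,,,lt,
ymc,al_bag_n2,25,0,0.25,,,lt,
ymc,al_bag_n2,25,4,0.25,,,lt,
ymc,al_bag_n2,25,8,0.25,,,lt,
ymc,al_bag_n2,25,12,0.25,,,lt,
ymc,al_bag_n2,25,16,0.25,,,lt,
ymc,al_bag_n2,25,20,0.25,,,lt,
ymc,al_bag_n2,25,24,0.25,,,lt,
ymc,al_bag_n2,35,0,0.25,,,lt,
ymc,al_bag_n2,35,4,0.25,,,lt,
ymc,al_bag_n2,35,8,0.25,,,lt,
ymc,al_bag_n2,35,12,0.25,,,lt,
ymc,al_bag_n2,35,16,0.25,,,lt,1
ymc,al_bag_n2,45,0,0.25,,,lt,
ymc,al_bag_n2,45,4,0.25,,,lt,
ymc,al_bag_n2,45,8,0.25,,,lt,
ymc,al_bag_n2,45,12,0.25,,,lt,
ymc,al_bag_n2,45,16,0.25,,,lt,1
ymc,al_bag_air,4,0,0.25,,,lt,
ymc,al_bag_air,4,4,0.25,,,lt,
ymc,al_bag_air,4,8,0.25,,,lt,
ymc,al_bag_air,4,12,0.25,,,lt,
ymc,al_bag_air,4,16,0.25,,,lt,
ymc,al_bag_air,4,20,0.25,,,lt,
ymc,al_bag_air,4,24,0.25,,,lt,
ymc,al_bag_air,25,0,0.25,,,lt,
ymc,al_bag_air,25,4,0.25,,,lt,
ymc,al_bag_air,25,8,0.25,,,lt,
ymc,al_bag_air,25,12,0.25,,,lt,
ymc,al_bag_air,25,16,0.25,,,lt,
ymc,al_bag_air,25,20,0.25,,,lt,
ymc,al_bag_air,25,24,0.25,,,lt,
ymc,al_bag_air,35,0,0.25,,,lt,
ymc,al_bag_air,35,4,0.25,,,lt,
ymc,al_bag_air,35,8,0.25,,,lt,
ymc,al_bag_air,35,12,0.25,,,lt,
ymc,al_bag_air,35,16,0.25,,,lt,1
ymc,al_bag_air,45,0,0.25,,,lt,
ymc,al_bag_air,45,4,0.25,,,lt,
ymc,al_bag_air,45,8,0.25,,,lt,
ymc,al_bag_air,45,12,0.25,,,lt,
ymc,al_bag_air,45,16,0.25,,,lt,1
ymc,clear_plastic,4,0,0.25,,,lt,
ymc,clear_plastic,4,4,0.25,,,lt,
ymc,clear_plastic,4,8,0.25,,,lt,
ymc,clear_plastic,4,12,0.25,,,lt,
ymc,clear_plastic,4,16,0.25,,,lt,
ymc,clear_plastic,4,20,0.25,,,lt,
ymc,clear_plastic,4,24,0.25,,,lt,
ymc,clear_plastic,25,0,0.25,,,lt,
ymc,clear_plastic,25,4,0.25,,,lt,
ymc,clear_plastic,25,8,0.25,,,lt,
ymc,clear_plastic,25,12,0.25,,,lt,
ymc,clear_plastic,25,16,0.25,,,lt,
ymc,clear_plastic,25,20,0.25,,,lt,
ymc,clear_plastic,25,24,0.25,,,lt,
ymc,clear_plastic,35,0,0.25,,,lt,
ymc,clear_plastic,35,4,0.25,,,lt,
ymc,clear_plastic,35,8,0.25,,,lt,
ymc,clear_plastic,35,12,0.25,,,lt,
ymc,clear_plastic,35,16,0.25,,,lt,1
ymc,clear_plastic,45,0,0.25,,,lt,
ymc,clear_plastic,45,4,0.25,,,lt,
ymc,clear_plastic,45,8,0.25,,,lt,
ymc,clear_plastic,45,12,0.25,,,lt,
ymc,clear_plastic,45,16,0.25,,,lt,1
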