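attribute,value,sd,n
overall_acceptance,6.2,1.4,50
color_acceptance,6.3,1.5,50
flavor_acceptance,6.0,1.7,50
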