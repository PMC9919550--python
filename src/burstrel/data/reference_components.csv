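study,timescale,component,value
study2_composite,momentary,person,0.871
study2_composite,momentary,occasion,0.008
study2_composite,momentary,item,4.639
study2_composite,momentary,person_x_occasion,0.094
study2_composite,momentary,person_x_item,0.381
study2_composite,momentary,occasion_x_item,0.000
study2_composite,momentary,error,1.409
study2_composite,momentary,m,3
study2_composite,daily,person,0.887
study2_composite,daily,occasion,0.016
study2_composite,daily,item,4.642
study2_composite,daily,person_x_occasion,0.057
study2_composite,daily,person_x_item,0.377
study2_composite,daily,occasion_x_item,0.000
study2_composite,daily,error,1.451
study2_composite,daily,m,12
study3_rspan,momentary,person,0.488
study3_rspan,momentary,occasion,0.007
study3_rspan,momentary,item,0.008
study3_rspan,momentary,person_x_occasion,0.177
study3_rspan,momentary,person_x_item,0.005
study3_rspan,momentary,occasion_x_item,0.000
study3_rspan,momentary,error,0.914
study3_rspan,momentary,m,3
study3_rspan,daily,person,0.486
study3_rspan,daily,occasion,0.009
study3_rspan,daily,item,0.008
study3_rspan,daily,person_x_occasion,0.064
study3_rspan,daily,person_x_item,0.001
study3_rspan,daily,occasion_x_item,0.000
study3_rspan,daily,error,1.032
study3_rspan,daily,m,15
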