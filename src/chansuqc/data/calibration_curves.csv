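analyte,compound_id,slope,intercept,r2,range_low_ug_ml,range_high_ug_ml,lod_ug_ml,loq_ug_ml
GB,gamabufotalin,8.5450,0.4726,0.9995,2.632,263.2,0.1053,0.3290
TBG,telocinobufagin,8.4668,-2.6368,0.9995,3.380,338.0,0.2253,0.6760
BFL,bufotalin,7.6345,-1.2852,0.9995,2.548,254.8,0.0849,0.2548
CFL,cinobufotalin,7.8537,-2.4578,0.9995,3.852,385.2,0.2568,0.7704
BL,bufalin,8.7099,-2.5159,0.9995,2.560,256.0,0.1024,0.3012
CBG,cinobufagin,7.9887,-3.5450,0.9994,4.208,420.8,0.2805,0.8416
RBG,resibufogenin,8.5660,-2.4699,0.9995,3.424,342.4,0.2283,0.6848
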