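varied_factor,varied_value,pH,enzyme_pct,time_min,temp_C,yield_pct
enzyme_pct,4.5,5,4.5,30,50,24.21
enzyme_pct,1.5,5,1.5,30,50,17.72
pH,5,5,3.0,30,50,20.57
temp_C,50,5,3.0,30,50,23.15
temp_C,60,5,3.0,30,60,23.16
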