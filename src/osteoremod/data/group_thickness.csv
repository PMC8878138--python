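group,mean_thickness_um,sd_um,duration_days,normalized
sedentary,957,110,56,1
continuous,708,65,56,0.74
intermittent,1024,112,56,1.07
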