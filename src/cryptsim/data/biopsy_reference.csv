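cell_type,mean,sd,cv_pct
quiescent_stem,35.7,36.3,102
proliferating,623.9,234.1,37.5
differentiated,1768.2,434.5,24.6
total,2427.8,504.4,20.8
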