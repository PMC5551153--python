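cultivar_group,pruning,lad
low,severe,2.5
low,normal,2.9
low,without_pruning,3.3
medium,severe,3.3
medium,normal,3.7
medium,without_pruning,4.1
high,severe,4.1
high,normal,4.6
high,without_pruning,5.0
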