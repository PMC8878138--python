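parameter,value
alpha_ob_W1,1.0009
alpha_oc_W1,1.0
alpha_ob_W3,1.0007
alpha_oc_W3,1.0
n_W1,13.6
n_W3,5
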