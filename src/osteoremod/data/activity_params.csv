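parameter,value,units
W0,3.1847e-4,mJ
W1,3.7e-4,mJ
W2,3.72e-4,mJ
W3,3.78e-4,mJ
k1,386.64e5,mg/(mJ mm^3 56 d)
k2,-375e5,mg/(mJ mm^3 56 d)
A1,1992.36,mg/(mm^3 56 d)
A2,-2232.38,mg/(mm^3 56 d)
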