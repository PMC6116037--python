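parent_region	deletion
CFA13:34034756-34423363	CFA13:34121352-34138888
CFA13:34034756-34423363	CFA13:34202633-34373142
CFA22:24782790-25362284	CFA22:24939999-25103044
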