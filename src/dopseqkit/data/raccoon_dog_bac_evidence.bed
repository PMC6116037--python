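CFA13	47079087	47478846	bac_kit_region
CFA20	24724662	25132678	bac_cfa20
CFA28	3855680	4240133	bac_cfa28
CFA13	34000000	34000001	bac_cfa13_34mbp_synthetic_point
CFA29	41000000	41000001	bac_cfa29_41mbp_synthetic_point
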