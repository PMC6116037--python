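region	VVUB2	VVUB3	VVUB5	VVUB6	evidence
CFA5:70796855-70973839	+	+	+
CFA6:75583707-76038617	+	+	+
CFA10:18252019-18487716	+	+	+
CFA12:48851593-49019024	+	+	+		+
CFA13:34034756-34423363	+	+	+	+	+
CFA13:47122582-47327423	+	+	+	+	+
CFA15:53805540-54125636	+	+	+	+	+
CFA19:41511154-44072972	+	+	+	+	+
CFA22:7086237-7370105	+	+	+	+
CFA22:24782790-25362284	+	+	+
CFA31:2880206-4129393	+	+	+	+	+
CFA32:14687852-15257168	+	+	+
CFA34:2522638-2767316	+	+	+	+	+
CFA34:15179149-15450638	+	+	+
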