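region	NPPB1	NPPB2	NPPB3	NPPB4	NPPB5	NPPB6	NPPB7	NPPB8	evidence
CFA1:207953-434482	+
CFA3:7233009-7672854	+	+	+	+	~	~	~	+
CFA3:30949630-31192570	+	+	+					+
CFA5:5213259-5517316	+					+
CFA5:60890426-60976094	+
CFA5:84586827-84980563	+							+
CFA13:47079087-47478846	+							+	+
CFA14:58162796-58517967	+
CFA15:58671318-58919401	+	+	+	~	+	+	+
CFA16:5042848-5239664	+	~	~	~		+		+
CFA16:50655536-50916841	+
CFA16:51357728-51710145	+
CFA19:28836248-29004558	+	+	+	+	~	+	+	+
CFA19:38810088-39213802	+	+	+			+	~	+
CFA20:24724662-25132678	+	+	+			~		+	+
CFA21:36289982-36390083	+	+	~			+	+
CFA23:47315786-47535793	+	+	+	~	+	+	+
CFA24:11660722-11768215	~					+
CFA24:43488879-43732408	~	~	~			+		~
CFA26:18769412-18964210	+
CFA27:31691325-31793171	+					+
CFA27:37050854-37410557	+	+	+	+	+	+	+	+
CFA28:3855680-4240133	+	+	+			+	+		+
CFA28:7498907-7656661	+	+	+	~		+	+	+
CFA29:28913684-29259138	+							+
CFA32:13104843-14881357	+					+
CFA38:1062270-1094480	+					+
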