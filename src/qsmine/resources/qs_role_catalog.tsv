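# qsmine packaged catalog mapping KO ids to QS/QQ component roles.
# K19666 (SolR, LuxR-family AHL receptor) is included here although it is
# absent from the 77-entry KO reference table; it is used for LuxR-homolog
# bookkeeping alongside K20334.
# Columns: ko_id	component	system
K13061	LuxI	AI-1
K20249	LuxI	AI-1
K19666	LuxR	AI-1
K20334	LuxR	AI-1
K07711	QseE	AI-3
K07715	QseF	AI-3
K07666	QseB	AI-3
K13816	RpfF	DSF
K10715	RpfC	DSF
K13815	RpfG	DSF
K01897	RpfB	DSF
K10914	Clp	DSF
K13075	AhlD	QQ
K10555	LsrB	AI-2
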