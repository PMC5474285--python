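IBD_CORE	Inflammatory bowel disease pathway, core cytokine/NF-kB axis (minimal excerpt)	IL1B	IL2	IL6	TNF	RELA	CHUK	TGFB1	JUN	STAT3
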