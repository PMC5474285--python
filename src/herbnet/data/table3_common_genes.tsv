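uniprot_id	protein_name	gene_symbol
Q92887	Canalicular multispecific organic anion transporter 1	ABCC2
O60218	Aldo-keto reductase family 1 member B10	AKR1B10
P09917	Arachidonate 5-lipoxygenase	ALOX5
P62158	Calmodulin	CALM1
Q00534	Cell division protein kinase 6	CDK6
P10145	Interleukin-8	CXCL8
Q99814	Endothelial PAS domain-containing protein 1	EPAS1
P01100	Proto-oncogene c-Fos	FOS
P47869	Gamma-aminobutyric-acid receptor alpha-2 subunit	GABRA2
P49841	Glycogen synthase kinase-3 beta	GSK3B
P09601	Heme oxygenase 1	HMOX1
P05362	Intercellular adhesion molecule 1	ICAM1
P01584	Interleukin-1 beta	IL1B
P05231	Interleukin-6	IL6
P03956	Interstitial collagenase	MMP1
Q15788	Nuclear receptor coactivator 1	NCOA1
P35228	Nitric oxide synthase, inducible	NOS2
P01111	GTPase NRas	NRAS
P11309	Proto-oncogene serine/threonine-protein kinase Pim-1	PIM1
P61925	cAMP-dependent protein kinase inhibitor alpha	PKIA
P00749	Urokinase-type plasminogen activator	PLAU
P35354	Prostaglandin G/H synthase 2	PTGS2
P40763	Signal transducer and activator of transcription 3	STAT3
P17752	Tryptophan 5-hydroxylase 1	TPH1
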