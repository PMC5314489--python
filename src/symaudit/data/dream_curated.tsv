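partner_symbol	partner_accession	partner_entry	year	reference	experimental_model	detection_method	notes	status
PSEN1	P49768	PSN1_HUMAN	1998	cite:46	in vitro: Y2H (PSEN bait, human brain cDNA); COS-7 cells	Y2H and co-precipitation followed by Western blot	Y2H in the same study could not confirm a PSEN2 interaction	supported
PSEN2	P49810	PSN2_HUMAN	1998	cite:46;cite:52	in vitro: COS-7 cells; SH-SY5Y cells	Co-localization and co-precipitation followed by Western blot	Interaction occurs in a Ca2+-independent manner	supported
KCNIP3	Q9Y2W7	CSEN_HUMAN	1996	cite:47;cite:53;cite:54	in vitro: CHO cells; HEK293 cells	Molecular mass from SDS-PAGE gels and Western blot	Multimeric forms described: monomers, dimers and tetramers	supported
CREM	Q03060	CREM_HUMAN	2000	cite:53	in vitro: HEK293, NB69, SK-NMC cells	Pull-down using CREM as bait	Interaction leads to loss of repressor binding to target genes	supported
KCNIP4	Q6PIL6	KCIP4_HUMAN	2000	cite:48	in vitro: Y2H, KCNIP4 as bait	Y2H and co-precipitation	Y2H cDNA library constructed from rat brain polyA+ RNA	supported
CREB1	P16220	CREB1_HUMAN	2002	cite:55	in vivo: rat brain nuclear extract; in vitro: HEK293, PC12 cells	Immunoprecipitation from brain nuclear extracts with anti-DREAM antibody	Interaction prevents CBP recruitment by phospho-CREB and affects CRE-dependent transcription	supported
NKX2-1	P43699	NKX21_HUMAN	2004	cite:56	in vivo: thyroid-derived FRTL-5 cells; in vitro: CHO cells	Co-precipitation using GST-DREAM as bait	Regulates expression of the thyroglobulin gene	supported
VDR	P11473	VDR_HUMAN	2005	cite:57;cite:58	in vitro: co-incubation of GST-DREAM and 6His-VDR	Pull-down after Ni-Sepharose incubation of a 1:1 protein mixture	Ca2+ induces DREAM dimerization and binding to VDR; chromatin immunoprecipitation shows DNA binding on vitamin D and retinoic acid response elements	supported
CtBP1	Q13363	CTBP1_HUMAN	2006	cite:59	in vitro: Y2H, DREAM as bait; co-immunoprecipitation in H4 cells	Y2H using N-terminus of DREAM as bait and co-precipitation	May modulate transcriptional repression of c-fos	supported
CtBP2	P56545	CTBP2_HUMAN	2006	cite:59	in vitro: Y2H, DREAM as bait; co-immunoprecipitation in H4 cells	Y2H using N-terminus of DREAM as bait and co-precipitation	May modulate transcriptional repression of c-fos	supported
GRK6	P43250	GRK6_HUMAN	2007	cite:60	in vitro: Y2H, DREAM as bait; co-immunoprecipitation in PC12 cells	Y2H confirmed by co-precipitation with GRK6-specific antibodies	A Ca2+-insensitive DREAM mutant was used to preclude Y2H artifacts	supported
ADRBK1	P25098	ARBK1_HUMAN	2007	cite:60	in vitro: co-immunoprecipitation in PC12 cells; HEK293	Co-precipitation of PC12 cell extracts	May regulate DREAM function through phosphorylation	supported
B3GALT2	O43825	B3GT2_HUMAN	2008	cite:61	in vitro: Y2H, mouse GalT2 bait, human brain cDNA; CHO-K1 cells	Y2H using N-terminus of GalT2 as bait	Involves trafficking of glycosyl-transferases to Golgi and endoplasmic reticulum	supported
TSHR	P16473	TSHR_HUMAN	2009	cite:62	in vivo: mouse thyroid glands; in vitro: CHO cells	Co-immunoprecipitation with hemagglutinin-tagged DREAM	Activation of cAMP signaling, thyroid enlargement and nodular development	supported
DLG4	P78352	DLG4_HUMAN	2010	cite:63	in vivo: mouse hippocampal extracts	Co-immunoprecipitation	Modulates postsynaptic NMDA receptor function, plasticity, learning and memory	supported
CACNA1H	O95180	CAC1H_HUMAN	2010	cite:64	in vivo: rat brain extracts	Co-immunoprecipitation	Rat brain protein extracts	supported
CACNA1I	Q9P0X4	CAC1I_HUMAN	2010	cite:64	in vivo: rat brain extracts	Co-immunoprecipitation	Rat brain protein extracts	supported
GRIN1	Q05586	NMDZ1_HUMAN	2010	cite:65	in vitro: HEK293 cells; in vivo: rat hippocampus extracts	Immunoprecipitation from rat hippocampus extracts	Supports a role in learning and memory	supported
UBE2I	P63279	UBC9_HUMAN	2011	cite:66	in vitro: Y2H, DREAM as bait, human brain cDNA; PC12 and HEK293 cells	Y2H and co-immunoprecipitation of PC12 cell extracts	Sumoylation regulates nuclear localization; Ca2+-insensitive DREAM mutant used	supported
Prdx3	P30048	PRDX3_HUMAN	2011	cite:54	in vitro: Y2H, Ca2+-insensitive DREAM bait, human bone marrow cDNA; COS-7 cells	Y2H and co-immunoprecipitation of CHO cell extracts	Mitochondrial protein; subcellular site of redox regulation uncharacterized	supported
CALM1	P62158	CALM_HUMAN	2012	cite:67	in vivo: rat brain extracts	Affinity capture followed by mass spectrometric identification	Binds DREAM in the presence of Ca2+; accession stored as printed in the source table	supported
PPP3R1	P63098	CANB1_HUMAN	2012	cite:67	in vivo: rat brain extracts	Affinity capture and mass spectrometric identification	Binds DREAM in the absence of Ca2+	supported
RCC1	P18754	RCC1_HUMAN	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive: listed by database retrieval, removed in a later release; no experimental evidence links it to the query protein	rejected
CSNK1G2		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive attributable to the shared kinase abbreviation CK; removed in a later database release	rejected
CSNK1D		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive attributable to the shared kinase abbreviation CK; removed in a later database release	rejected
CSNK1A1		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive attributable to the shared kinase abbreviation CK; removed in a later database release	rejected
CSNK1E		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive attributable to the shared kinase abbreviation CK; removed in a later database release	rejected
CSNK1AIL		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive; symbol stored verbatim as listed by the database	rejected
CSNK1G1		-	2013	db:STRING-9.0	in silico retrieval only	Database co-mention / text mining	False positive attributable to the shared kinase abbreviation CK; removed in a later database release	rejected
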