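# Interaction list synthesized from the curated DREAM (KCNIP3, Q9Y2W7) evidence table.
# 15-column PSI-MITAB 2.5; one line per curated supported partner, including the self-association row.
uniprotkb:Q9Y2W7	uniprotkb:P49768	-	-	-	-	Y2H and co-precipitation followed by Western blot	-	cite:46	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P49810	-	-	-	-	Co-localization and co-precipitation followed by Western blot	-	cite:46	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q9Y2W7	-	-	-	-	Molecular mass from SDS-PAGE gels and Western blot	-	cite:47	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q03060	-	-	-	-	Pull-down using CREM as bait	-	cite:53	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q6PIL6	-	-	-	-	Y2H and co-precipitation	-	cite:48	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P16220	-	-	-	-	Immunoprecipitation from brain nuclear extracts with anti-DREAM antibody	-	cite:55	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P43699	-	-	-	-	Co-precipitation using GST-DREAM as bait	-	cite:56	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P11473	-	-	-	-	Pull-down after Ni-Sepharose incubation	-	cite:57	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q13363	-	-	-	-	Y2H using N-terminus of DREAM as bait and co-precipitation	-	cite:59	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P56545	-	-	-	-	Y2H using N-terminus of DREAM as bait and co-precipitation	-	cite:59	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P43250	-	-	-	-	Y2H confirmed by co-precipitation	-	cite:60	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P25098	-	-	-	-	Co-precipitation of PC12 cell extracts	-	cite:60	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:O43825	-	-	-	-	Y2H using N-terminus of GalT2 as bait	-	cite:61	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P16473	-	-	-	-	Co-immunoprecipitation with hemagglutinin-tagged DREAM	-	cite:62	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P78352	-	-	-	-	Co-immunoprecipitation	-	cite:63	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:O95180	-	-	-	-	Co-immunoprecipitation	-	cite:64	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q9P0X4	-	-	-	-	Co-immunoprecipitation	-	cite:64	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:Q05586	-	-	-	-	Immunoprecipitation from rat hippocampus extracts	-	cite:65	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P63279	-	-	-	-	Y2H and co-immunoprecipitation of PC12 cell extracts	-	cite:66	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P30048	-	-	-	-	Y2H and co-immunoprecipitation of CHO cell extracts	-	cite:54	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P62158	-	-	-	-	Affinity capture followed by mass spectrometric identification	-	cite:67	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
uniprotkb:Q9Y2W7	uniprotkb:P63098	-	-	-	-	Affinity capture and mass spectrometric identification	-	cite:67	taxid:9606(human)	taxid:9606(human)	-	curated-literature	-	-
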