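gene_id,symbol,synonyms,locus_type,description
1119,CHKA,CHK;CKI;CK;EK,protein-coding,Choline kinase alpha (CK; EK)
1120,CHKB,CHKL,protein-coding,Choline kinase beta
1111,CHEK1,CHK1;CHK,protein-coding,Checkpoint kinase 1
11200,CHEK2,CHK2;CDS1,protein-coding,Checkpoint kinase 2
4145,MATK,CHK;CTK;HYL,protein-coding,Megakaryocyte-associated tyrosine kinase
1452,CSNK1A1,CKI;CK,protein-coding,Casein kinase I isoform alpha
1453,CSNK1D,HCKID,protein-coding,Casein kinase I isoform delta
1454,CSNK1E,HCKIE,protein-coding,Casein kinase I isoform epsilon
1455,CSNK1G2,,protein-coding,Casein kinase I isoform gamma-2
53944,CSNK1G1,,protein-coding,Casein kinase I isoform gamma-1
900001,CSNK1AIL,,protein-coding,Casein kinase I family entry (symbol preserved verbatim from an interaction-database listing; synthetic gene id)
1457,CSNK2A1,CK2A1;CKII;CK,protein-coding,Casein kinase II subunit alpha
2080,PPIA,PPIASE;CYPA,protein-coding,"Peptidyl-prolyl cis-trans isomerase A (PPIase A, cyclophilin A)"
2081,PPIB,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase B (PPIase B)
2086,PPIC,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase C (PPIase C)
2287,FKBP2,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
2288,FKBP3,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
2289,FKBP4,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
8468,FKBP6,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
11328,FKBP9,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
51645,PPIL1,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase)-like 1
51661,FKBP7,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
60681,FKBP10,PPIASE,protein-coding,Peptidyl-prolyl cis-trans isomerase (PPIase) FK506-binding family
7369,UMOD,THP,protein-coding,"Uromodulin (Tamm-Horsfall urinary glycoprotein, THP)"
30818,KCNIP3,CSEN;DREAM;KCHIP3,protein-coding,Kv channel-interacting protein 3 (calsenilin; DREAM)
900002,CHKAP1,,pseudogene,Choline kinase alpha pseudogene (synthetic placeholder row)
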