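accession,secondary_accessions,entry_name,description,gene_id
P35790,,CHKA_HUMAN,Choline kinase alpha,1119
P07911,Q540J6;Q6ZS84;Q8IYG0,UROM_HUMAN,"Uromodulin (Tamm-Horsfall urinary glycoprotein)",7369
P18754,,RCC1_HUMAN,Regulator of chromosome condensation 1,
Q9Y2W7,,CSEN_HUMAN,"Calsenilin (DRE-antagonist modulator, DREAM; Kv channel-interacting protein 3, KChIP3)",30818
P49768,,PSN1_HUMAN,"Presenilin-1, Protein S182",
P49810,,PSN2_HUMAN,"Presenilin-2, AD3LP, AD5, E5-1, STM-2",
Q03060,,CREM_HUMAN,"cAMP-responsive element modulator, inducible cAMP early repressor (ICER)",
Q6PIL6,,KCIP4_HUMAN,"Kv channel-interacting protein 4 (KChIP4), calsenilin-like protein",
P16220,,CREB1_HUMAN,Cyclic AMP-responsive element-binding protein 1,
P43699,,NKX21_HUMAN,"Homeobox protein Nkx-2.1, thyroid transcription factor 1",
P11473,,VDR_HUMAN,"Vitamin D3 receptor, 1,25-dihydroxyvitamin D3 receptor",
Q13363,,CTBP1_HUMAN,C-terminal-binding protein 1,
P56545,,CTBP2_HUMAN,C-terminal-binding protein 2,
P43250,,GRK6_HUMAN,G protein-coupled receptor kinase 6,
P25098,,ARBK1_HUMAN,"Beta-adrenergic receptor kinase 1, G-protein coupled receptor kinase 2",
O43825,,B3GT2_HUMAN,"Beta-1,3-galactosyltransferase 2",
P16473,,TSHR_HUMAN,"Thyrotropin receptor, thyroid-stimulating hormone receptor",
P78352,,DLG4_HUMAN,"Disks large homolog 4, postsynaptic density protein 95",
O95180,,CAC1H_HUMAN,Voltage-dependent T-type calcium channel subunit alpha-1H,
Q9P0X4,,CAC1I_HUMAN,Voltage-dependent T-type calcium channel subunit alpha-1I,
Q05586,,NMDZ1_HUMAN,"Glutamate receptor ionotropic, NMDA receptor subunit zeta-1",
P63279,,UBC9_HUMAN,SUMO-conjugating enzyme UBC9,
P30048,,PRDX3_HUMAN,"Thioredoxin-dependent peroxide reductase, mitochondrial (peroxiredoxin-3)",
P62158,,CALM_HUMAN,Calmodulin,
P63098,,CANB1_HUMAN,Calcineurin subunit B type 1,
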