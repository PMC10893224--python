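# Published per-venom-category gene-cluster counts for the Entacmaea
# quadricolor tentacle transcriptome and milked-venom proteome, used as the
# worked example: every derived percentage in the summaries is arithmetic on
# these counts.
category	rna_clusters	rna_families	protein_clusters	protein_families
Allergen and innate immunity	9	3	4	2
Auxiliary	67	1	19	1
Haemostatic and haemorrhagic	409	5	55	5
Mixed function enzymes	24	1	1	1
Neurotoxins	122	9	21	5
Pore forming	45	5	16	4
Protease inhibitors	38	2	5	1
Unknown	537	16	109	11
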