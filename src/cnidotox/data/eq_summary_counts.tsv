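# Published transcriptome/proteome summary counts for Entacmaea quadricolor
# (RNA gene-cluster universe vs milked-venom protein universe).
metric	rna	protein
orf_sequences	279274	5375
annotated_orfs	72218	5213
orfs_with_go_terms	46288	3901
unique_best_hit_subjects	18469	3718
orfs_with_signal	11807	1224
putative_toxin_orfs	1251	230
toxin_orfs_with_signal	515	149
toxin_unique_best_hit_subjects	296	124
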