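# Eight trans-Beringian bird lineage pairs: number of variable one-SNP-per-
# locus UCE loci, full dataset size (diploid individuals per population), and
# published Weir-Cockerham-style F_ST between the paired populations.
lineage	variable_loci	full_size	fst
Clangula_hyemalis	2442	7	0.004
Anas_crecca	2481	6	0.02
Mareca_penelope_americana	2315	8	0.044
Numenius_phaeopus	2388	7	0.269
Tringa_brevipes_incana	1636	8	0.585
Luscinia_svecica	2516	7	0.014
Pinicola_enucleator	2656	7	0.442
Pica_pica_hudsonia	2199	7	0.328
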