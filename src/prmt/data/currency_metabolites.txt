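# Default currency-metabolite blacklist (KEGG compound ids).
# Water, di-/tri-phosphonucleotides and ubiquitous cofactors are removed
# from the reaction network as non-specific to particular metabolic
# processes. Override with your own file for non-KEGG catalogs.
C00001	# H2O
C00002	# ATP
C00008	# ADP
C00044	# GTP
C00035	# GDP
C00063	# CTP
C00112	# CDP
C00075	# UTP
C00015	# UDP
C00459	# dTTP
C00363	# dTDP
C00003	# NAD+
C00004	# NADH
C00006	# NADP+
C00005	# NADPH
C00016	# FAD
C01352	# FADH2
C00010	# CoA
C00080	# H+
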