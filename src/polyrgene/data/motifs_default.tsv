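# Default R-gene-associated motif set (stand-in fixture).
# Patterns use one-letter amino-acid codes with 'x' as a single-residue
# wildcard and [..] alternatives. Motif names follow the conserved NB-ARC /
# TIR / LRR sequence features commonly used for R-gene screening.
motif_id	pattern
P-loop	GxGKTT
Kinase-2	LLVLDDV
Kinase-3a	GSRIII
GLPL	GLPLAL
RNBS-A	FDLxAWVCVSQ
RNBS-B	KYLVVLDDVW
RNBS-D	CFLYCALFP
MHDV	MHDVV
TIR-1	WxYDVFLSFRG
LRR-core	LxxLxLxx
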