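# Default peptide-binding-site mask for the MHC class IIbeta exon-2 amplicon.
# 1-based codon indices on the amplicon. Derived from the human HLA-DRbeta1
# peptide-contact residue set of the DR1 crystal structure (residues 9, 11,
# 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67, 68, 70, 71, 74,
# 78, 81, 82, 85, 86, 89, 90) mapped onto the amplicon assuming amplicon
# codon 1 corresponds to beta1 residue 5 (the amplicon spans >93% of exon 2,
# starting a few codons into the domain). Contacts beyond the amplicon span
# are ignored at load time. Replaceable via the pbs-mask option.
5
7
9
22
24
26
28
33
34
43
52
53
56
57
61
63
64
66
67
70
74
77
78
81
82
85
86
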