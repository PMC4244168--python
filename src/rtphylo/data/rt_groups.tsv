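# rtphylo controlled vocabulary of bacterial RT group labels, v1
# label: the value accepted in metadata group_label columns
# lineage: the top-level group the label belongs to
label	lineage
group_II	group_II
GII-A	group_II
GII-B	group_II
GII-C	group_II
GII-D	group_II
GII-E	group_II
GII-F	group_II
GII-CL	group_II
GII-ML	group_II
GII-g1	group_II
GII-g2	group_II
GII-g3	group_II
GII-g4	group_II
GII-g5	group_II
GII-g6	group_II
retron	retron
DGR	DGR
Abi	Abi
AbiK	Abi
Abi-P2	Abi
UN1	Abi
UN2	Abi
UN3	Abi
UN4	Abi
UN5	Abi
UG1	Abi
UG7	Abi
UG8	Abi
UG9	Abi
CRISPR-RT	CRISPR-RT
CRISPR-RT1	CRISPR-RT
CRISPR-RT2	CRISPR-RT
CRISPR-RT3	CRISPR-RT
CRISPR-RT4	CRISPR-RT
CRISPR-RT5	CRISPR-RT
CRISPR-RT6	CRISPR-RT
CRISPR-RT7	CRISPR-RT
G2L4	G2L4
UG2	UG2
UG3	UG3
UG4	UG4
UG5	UG5
UG6	UG6
UG10	UG10
UG11	UG11
UNC	UNC
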