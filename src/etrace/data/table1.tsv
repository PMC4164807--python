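bace1_resname	bace1_resnum	bace1_status	bace2_resname	bace2_resnum	bace2_status
SER	10	conserved
GLY	11	conserved
GLN	12	conserved
GLY	13	conserved
LEU	30	conserved	LEU	46	conserved
ASP	32	conserved	ASP	48	conserved
GLY	34	conserved	GLY	50	conserved
SER	35	conserved	SER	51	conserved
VAL	69	conserved	VAL	85	conserved
PRO	70	group-specific	LYS	86	group-specific
TYR	71	conserved	TYR	87	conserved
THR	72	conserved	THR	88	conserved
GLN	73	conserved	GLN	89	conserved
			GLN	90	conserved
PHE	108	conserved	PHE	124	conserved
ILE	110	group-specific	LEU	126	group-specific
TRP	115	conserved	TRP	131	conserved
ILE	118	conserved	ILE	134	conserved
ILE	126	group-specific	LEU	142	group-specific
TYR	198	conserved	TYR	211	conserved
LYS	224	conserved
ILE	226	conserved	ILE	239	conserved
ASP	228	conserved	ASP	241	conserved
GLY	230	conserved	GLY	243	conserved
THR	231	conserved	THR	244	conserved
THR	232	conserved	THR	245	conserved
ASN	233	group-specific	LEU	246	group-specific
ARG	235	conserved	ARG	248	conserved
THR	329	conserved
			SER	337	conserved
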