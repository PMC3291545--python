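# Hydration propensities h per protein atom type, keyed (residue, atom name);
# '*' wildcards the residue.  h is the empirical fraction of surface-exposed
# occurrences of the atom type that carry an ordered water (dimensionless).
# These are representative defaults ordered the way surface-hydration surveys
# rank atom classes (charged O/N > hydroxyl > amide > backbone N/O > sulfur);
# replace with a published table for production use.  Carbon propensity l is
# derived from the element (1 for C, else 0) and is not tabulated here.
*	N	0.26
*	O	0.50
*	OXT	0.78
SER	OG	0.69
THR	OG1	0.63
TYR	OH	0.60
ASP	OD1	0.81
ASP	OD2	0.81
GLU	OE1	0.83
GLU	OE2	0.83
ASN	OD1	0.72
ASN	ND2	0.54
GLN	OE1	0.70
GLN	NE2	0.52
HIS	ND1	0.54
HIS	NE2	0.56
LYS	NZ	0.95
ARG	NE	0.52
ARG	NH1	0.73
ARG	NH2	0.73
TRP	NE1	0.31
CYS	SG	0.17
MET	SD	0.10
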