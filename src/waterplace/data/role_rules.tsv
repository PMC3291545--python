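# Hydrogen-bond role rules keyed (residue, atom name); '*' wildcards the residue.
# roles column: comma-separated subset of hbond_donor, hbond_acceptor.
*	N	hbond_donor
*	O	hbond_acceptor
*	OXT	hbond_acceptor
SER	OG	hbond_donor,hbond_acceptor
THR	OG1	hbond_donor,hbond_acceptor
TYR	OH	hbond_donor,hbond_acceptor
ASP	OD1	hbond_acceptor
ASP	OD2	hbond_acceptor
GLU	OE1	hbond_acceptor
GLU	OE2	hbond_acceptor
ASN	OD1	hbond_acceptor
ASN	ND2	hbond_donor
GLN	OE1	hbond_acceptor
GLN	NE2	hbond_donor
HIS	ND1	hbond_donor,hbond_acceptor
HIS	NE2	hbond_donor,hbond_acceptor
LYS	NZ	hbond_donor
ARG	NE	hbond_donor
ARG	NH1	hbond_donor
ARG	NH2	hbond_donor
TRP	NE1	hbond_donor
CYS	SG	hbond_donor,hbond_acceptor
MET	SD	hbond_acceptor
HOH	O	hbond_donor,hbond_acceptor
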