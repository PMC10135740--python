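# Default per-residue ion-interaction sites.
#
# One carbon atom per residue, chosen two bonds away (heavy-atom graph)
# from the residue's principal ion donor/acceptor atom, so that an ion
# coordinating the donor/acceptor sits inside the 0.70 nm shell of the
# site.  The anchor column documents the donor/acceptor each site is two
# bonds from.  This table is a reconstruction from standard amino-acid
# connectivity and is fully overridable by the user (pass any file with
# the same layout).
#
# resname	site_atoms	anchor
LYS	CD	NZ (side-chain amine)
ARG	CD	NH1/NH2/NE (guanidinium)
ASP	CB	OD1/OD2 (carboxylate)
GLU	CG	OE1/OE2 (carboxylate)
HIS	CB	ND1 (imidazole)
HIE	CB	ND1 (imidazole)
HID	CB	NE2 (imidazole)
HIP	CB	ND1/NE2 (imidazolium)
SER	CA	OG (hydroxyl)
THR	CA	OG1 (hydroxyl)
TYR	CZ	OH (phenol)
ASN	CB	OD1/ND2 (amide)
GLN	CG	OE1/NE2 (amide)
CYS	CA	SG (thiol)
TRP	CD1	NE1 (indole)
MET	CB	SD (thioether)
# residues with no side-chain donor/acceptor: the backbone carbonyl O and
# amide N are anchored via the alpha-carbon
ALA	CA	backbone O/N
GLY	CA	backbone O/N
VAL	CA	backbone O/N
LEU	CA	backbone O/N
ILE	CA	backbone O/N
PRO	CA	backbone O/N
PHE	CA	backbone O/N
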