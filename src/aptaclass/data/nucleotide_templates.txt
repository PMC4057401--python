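# Hydrogen-suppressed 2'-deoxyribonucleoside templates, one residue per base.
# ATOM  <base> <atom_name> <element>
# BOND  <base> <atom_1> <atom_2> <order>
# Atom order within a residue is canonical (sugar first, then base) and
# defines vertex ordering in assembled graphs. Bond orders are recorded for
# chemical fidelity but descriptor computations use the simple unweighted
# graph. Phosphodiester linkage atoms (P, OP1, OP2) are added at assembly
# time between consecutive residues; termini are 5'-OH / 3'-OH.
# Attachment atoms for the backbone are O5' (5' side) and O3' (3' side).

# --- shared 2'-deoxyribose (8 heavy atoms), repeated per base block ---

ATOM A C1' C
ATOM A C2' C
ATOM A C3' C
ATOM A C4' C
ATOM A C5' C
ATOM A O4' O
ATOM A O3' O
ATOM A O5' O
ATOM A N9 N
ATOM A C8 C
ATOM A N7 N
ATOM A C5 C
ATOM A C6 C
ATOM A N6 N
ATOM A N1 N
ATOM A C2 C
ATOM A N3 N
ATOM A C4 C
BOND A C1' C2' 1
BOND A C2' C3' 1
BOND A C3' C4' 1
BOND A C4' O4' 1
BOND A O4' C1' 1
BOND A C3' O3' 1
BOND A C4' C5' 1
BOND A C5' O5' 1
BOND A C1' N9 1
BOND A N9 C8 1
BOND A C8 N7 2
BOND A N7 C5 1
BOND A C5 C6 2
BOND A C6 N6 1
BOND A C6 N1 1
BOND A N1 C2 2
BOND A C2 N3 1
BOND A N3 C4 2
BOND A C4 C5 1
BOND A C4 N9 1

ATOM G C1' C
ATOM G C2' C
ATOM G C3' C
ATOM G C4' C
ATOM G C5' C
ATOM G O4' O
ATOM G O3' O
ATOM G O5' O
ATOM G N9 N
ATOM G C8 C
ATOM G N7 N
ATOM G C5 C
ATOM G C6 C
ATOM G O6 O
ATOM G N1 N
ATOM G C2 C
ATOM G N2 N
ATOM G N3 N
ATOM G C4 C
BOND G C1' C2' 1
BOND G C2' C3' 1
BOND G C3' C4' 1
BOND G C4' O4' 1
BOND G O4' C1' 1
BOND G C3' O3' 1
BOND G C4' C5' 1
BOND G C5' O5' 1
BOND G C1' N9 1
BOND G N9 C8 1
BOND G C8 N7 2
BOND G N7 C5 1
BOND G C5 C6 1
BOND G C6 O6 2
BOND G C6 N1 1
BOND G N1 C2 1
BOND G C2 N2 1
BOND G C2 N3 2
BOND G N3 C4 1
BOND G C4 C5 2
BOND G C4 N9 1

ATOM C C1' C
ATOM C C2' C
ATOM C C3' C
ATOM C C4' C
ATOM C C5' C
ATOM C O4' O
ATOM C O3' O
ATOM C O5' O
ATOM C N1 N
ATOM C C2 C
ATOM C O2 O
ATOM C N3 N
ATOM C C4 C
ATOM C N4 N
ATOM C C5 C
ATOM C C6 C
BOND C C1' C2' 1
BOND C C2' C3' 1
BOND C C3' C4' 1
BOND C C4' O4' 1
BOND C O4' C1' 1
BOND C C3' O3' 1
BOND C C4' C5' 1
BOND C C5' O5' 1
BOND C C1' N1 1
BOND C N1 C2 1
BOND C C2 O2 2
BOND C C2 N3 1
BOND C N3 C4 2
BOND C C4 N4 1
BOND C C4 C5 1
BOND C C5 C6 2
BOND C C6 N1 1

ATOM T C1' C
ATOM T C2' C
ATOM T C3' C
ATOM T C4' C
ATOM T C5' C
ATOM T O4' O
ATOM T O3' O
ATOM T O5' O
ATOM T N1 N
ATOM T C2 C
ATOM T O2 O
ATOM T N3 N
ATOM T C4 C
ATOM T O4 O
ATOM T C5 C
ATOM T C7 C
ATOM T C6 C
BOND T C1' C2' 1
BOND T C2' C3' 1
BOND T C3' C4' 1
BOND T C4' O4' 1
BOND T O4' C1' 1
BOND T C3' O3' 1
BOND T C4' C5' 1
BOND T C5' O5' 1
BOND T C1' N1 1
BOND T N1 C2 1
BOND T C2 O2 2
BOND T C2 N3 1
BOND T N3 C4 1
BOND T C4 O4 2
BOND T C4 C5 1
BOND T C5 C7 1
BOND T C5 C6 2
BOND T C6 N1 1
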