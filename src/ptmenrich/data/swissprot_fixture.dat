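ID   KIN1_HUMAN              Reviewed;         400 AA.
AC   P99901; Q00001;
OS   Homo sapiens (Human).
KW   Phosphoprotein; Acetylation; Reference proteome.
FT   MOD_RES         15
FT                   /note="O-phospho-L-threonine; by AURKB"
FT   MOD_RES         44
FT                   /note="N6-acetyl-L-lysine"
//
ID   KIN2_HUMAN              Reviewed;         350 AA.
AC   P99902;
OS   Homo sapiens (Human).
KW   Phosphoprotein; Reference proteome.
FT   MOD_RES         21
FT                   /note="O-phospho-L-serine; by PKA"
FT   MOD_RES         87
FT                   /note="O4-phospho-L-tyrosine"
//
ID   UBC1_HUMAN              Reviewed;         300 AA.
AC   P99903;
OS   Homo sapiens (Human).
KW   Ubl conjugation; Reference proteome.
FT   CROSSLNK        48
FT                   /note="Glycyl lysine isopeptide (Lys-Gly) (interchain
FT                   with G-Cter in ubiquitin)"
//
ID   MEMB1_HUMAN             Reviewed;         250 AA.
AC   P99904;
OS   Homo sapiens (Human).
KW   Lipoprotein; Glycoprotein; Reference proteome.
FT   LIPID           3
FT                   /note="S-palmitoyl-L-cysteine"
//
ID   HOUS1_HUMAN             Reviewed;         200 AA.
AC   P99905;
OS   Homo sapiens (Human).
KW   Reference proteome.
//
ID   ACTB_MOUSE              Reviewed;         375 AA.
AC   Q99906;
OS   Mus musculus (Mouse).
KW   Phosphoprotein; Methylation; Reference proteome.
FT   MOD_RES         73
FT                   /note="Omega-N-methyl-L-arginine"
//
ID   NAKD1_MOUSE             Reviewed;         180 AA.
AC   Q99907; Q00002; Q00003;
OS   Mus musculus (Mouse).
KW   Acetylation; Reference proteome.
FT   MOD_RES         1
FT                   /note="N-acetyl-L-methionine"
//
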