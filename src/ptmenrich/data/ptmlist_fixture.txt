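----------------------------------------------------------------------------
        Synthetic excerpt in the style of the UniProt PTM controlled
        vocabulary (ptmlist), for testing and worked examples.  Mass
        deltas are the standard values for these modification classes;
        PTM-#### accession codes are assigned locally.
----------------------------------------------------------------------------
ID   O-phospho-L-threonine.
AC   PTM-0001
FT   MOD_RES
TG   Threonine.
PP   Anywhere.
CF   H O3 P
MM   79.966331
MA   79.98
KW   Phosphothreonine.
//
ID   O-phospho-L-serine.
AC   PTM-0002
FT   MOD_RES
TG   Serine.
PP   Anywhere.
CF   H O3 P
MM   79.966331
MA   79.98
KW   Phosphoserine.
//
ID   O4-phospho-L-tyrosine.
AC   PTM-0003
FT   MOD_RES
TG   Tyrosine.
PP   Anywhere.
CF   H O3 P
MM   79.966331
MA   79.98
KW   Phosphotyrosine.
//
ID   N6-acetyl-L-lysine.
AC   PTM-0004
FT   MOD_RES
TG   Lysine.
PP   Anywhere.
CF   C2 H2 O
MM   42.010565
MA   42.04
KW   N6-acetyllysine.
//
ID   N-acetyl-L-alanine.
AC   PTM-0005
FT   MOD_RES
TG   Alanine.
PP   Protein N-terminus.
CF   C2 H2 O
MM   42.010565
MA   42.04
KW   N-acetylalanine.
//
ID   N-acetyl-L-methionine.
AC   PTM-0006
FT   MOD_RES
TG   Methionine.
PP   Protein N-terminus.
CF   C2 H2 O
MM   42.010565
MA   42.04
KW   N-acetylmethionine.
//
ID   Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin).
AC   PTM-0007
FT   CROSSLNK
TG   Lysine-Glycine.
PP   Anywhere.
CF   C2 H3 N O
MM   114.042927
MA   114.10
KW   Ubl conjugation.
//
ID   S-palmitoyl-L-cysteine.
AC   PTM-0008
FT   LIPID
TG   Cysteine.
PP   Anywhere.
CF   C16 H30 O
MM   238.229666
MA   238.41
KW   Palmitoylation.
//
ID   N4-glycosyl-L-asparagine.
AC   PTM-0009
FT   MOD_RES
TG   Asparagine.
PP   Anywhere.
KW   Glycoprotein.
//
ID   Omega-N-methyl-L-arginine.
AC   PTM-0010
FT   MOD_RES
TG   Arginine.
PP   Anywhere.
CF   C H2
MM   14.015650
MA   14.03
KW   Methylation.
//
ID   Blocked amino end (Ser).
AC   PTM-0011
FT   MOD_RES
TG   Serine.
PP   Protein N-terminus.
//
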