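# Supplementary PTM-category keywords (protein-level umbrella terms that the
# controlled vocabulary does not list as KW cross-references of a single
# exact modification).  One keyword per line.
Phosphoprotein
Glycoprotein
Acetylation
Methylation
Lipoprotein
Disulfide bond
Ubl conjugation
Hydroxylation
Isopeptide bond
Zymogen
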