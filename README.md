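# ptmenrich

PTM-centric enrichment analysis for mass-spectrometry proteomics.

Most shotgun proteomics experiments search spectra with only a handful of
routine variable modifications, so posttranslational modifications (PTMs)
relevant to the biology under study are simply never looked for. `ptmenrich`
predicts which PTMs matter in a given experiment *from the protein-level
results alone*: it annotates each protein with curated PTM terms (from
Swiss-Prot keywords and MOD_RES/CROSSLNK/LIPID feature annotations), tests
whether any PTM term is statistically concentrated among the regulated
proteins, and exports the corresponding exact chemical modifications so a
second, refined database search can go hunting for them.

It is written for proteomics data analysts who have a differential-expression
table (or just a protein list) and want a principled shortlist of variable
modifications for the next search round.

## Statistics

**SEA (singular enrichment analysis).** For a population of N annotated
proteins of which K carry a PTM term, and a query list of n proteins of which
m carry it, the over-representation p-value is the hypergeometric upper tail

    p = Σ_{x=m}^{min(K,n)} C(K,x) C(N−K,n−x) / C(N,n),

adjusted across terms (Benjamini–Hochberg by default).

**PSEA (protein set enrichment analysis).** Proteins are ranked by a score
(default: sign(log2FC)·(−log10 p) from an equal-variance t-test). A weighted,
signed Kolmogorov–Smirnov running sum walks the ranked list: position i adds
|r_i|^p / N_R when protein i carries the term and subtracts 1/(N−N_H)
otherwise. The enrichment score ES is the maximal deviation from zero;
significance comes from uniformly permuting scores (default 1000 times), with
a same-sign normalized score NES = ES / mean |null ES|, a permutation FDR q
from the pooled null NES, and the leading-edge proteins (the members at or
before the running-sum peak) reported per term.

**Occupancy monitoring.** Modified-peptide intensities are normalized first by
channel total, then by the same protein's unmodified peptides, so
protein-level abundance changes cancel and what remains is the modification's
occupancy trend across conditions.

## Worked example

```python
import ptmenrich as pe

vocab = pe.parse_ptm_vocabulary(pe.packaged_data_path("ptmlist_fixture.txt"))
universe = vocab.keywords | set(
    pe.read_keyword_list(pe.packaged_data_path("ptm_keywords.txt")))
records = pe.parse_flatfile_records(pe.packaged_data_path("swissprot_fixture.dat"))
db = pe.build_database(records, vocab, universe)

cfg = pe.SimulationConfig()          # 500 proteins, planted "Phosphothreonine"
sdb, _ = pe.simulate_database(cfg)
scored, truth = pe.simulate_scored_list(sdb, cfg)
report = pe.run_psea(sdb, scored, n_perm=200, seed=1)
top = report.results[0]
print(top.term, round(top.nes, 3), top.nominal_p)

export = pe.psea2mass(report.results, vocab, alpha=0.05, top_k=5)
print(export.names())
```

prints

```
Phosphothreonine 2.685 0.004975124378109453
['O-phospho-L-threonine']
```

i.e. the planted term attains the top normalized enrichment score with the
smallest achievable permutation p at 200 permutations ((1+0)/(1+200)), and the
export maps the enriched keyword to the exact modification
(+79.966331 Da on threonine) ready for a refined search configuration.

The same pipeline is available from the shell:

```
ptmenrich simulate --seed 3 --out sim/
ptmenrich build-db --flatfile sim/proteins.dat --ptmlist sim/ptmlist.txt --out db/
ptmenrich psea --db db/annotation.db.gz --scores sim/scores.tsv \
    --n-perm 1000 --seed 7 --out psea/
ptmenrich to-mods --results psea/psea_results.tsv --ptmlist sim/ptmlist.txt \
    --alpha 0.05 --top-k 5 --out mods/
```

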