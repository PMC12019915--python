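# Methods

## Annotation model

A protein's PTM profile is taken entirely from curated annotation, never from
spectra: the build reduces each reviewed flat-file record to accessions (AC),
organism (OS), keywords (KW) and features (FT), and derives the PTM-term set
as

* the KW keywords that belong to the PTM keyword universe (the controlled
  vocabulary's parent keywords plus an optional supplementary keyword list
  for umbrella terms such as "Phosphoprotein" or "Glycoprotein" that are
  protein-level keywords rather than KW cross-references of a single exact
  modification), together with
* the parent keyword of every MOD_RES, CROSSLNK or LIPID feature whose
  `/note` text — truncated at the first ";" to drop "; by KINASE" and
  evidence suffixes — exactly (case-sensitively) matches a
  controlled-vocabulary modification name.

Proteins with no PTM terms stay in the database: they are real population
members and belong in the denominator N of both tests. Secondary accessions
resolve as aliases to the primary record and isoform suffixes ("P12345-2")
are stripped before lookup, because annotation is per canonical entry.
Organism scoping is a case-insensitive substring match on the OS taxonomy
name; SEA and PSEA use whatever database they are handed, so the population
is the organism slice by default and can be the full build or a
detected-proteome background simply by passing that database instead.

Only the current FT dialect (`/note="…"` qualifiers) is parsed; the pre-2019
columnar dialect is rejected outright rather than half-supported. The
database serialization is versioned gzip-JSON with an embedded checksum and,
deliberately, no wall-clock timestamp: identical inputs must give
byte-identical files so pipeline runs can be compared by hash.

## SEA

Upper-tail hypergeometric test per term: p = Σ_{x=m}^{min(K,n)}
C(K,x)C(N−K,n−x)/C(N,n), evaluated through the survival function rather than
naive summation. Over-representation only — the one-sided upper tail is the
question a refined search asks. Terms need a population count K of at least
`min_population_count` (default 5) to be reported; rarer terms produce
degenerate single-protein "enrichments" that no search configuration should
chase. Adjustment (default Benjamini–Hochberg; Bonferroni, Holm and none
available) runs across exactly the reported terms.

## PSEA

Given proteins ranked by descending score (ties broken by accession so runs
are reproducible; duplicated accessions keep the largest-magnitude score),
the running sum for a term with listed members H, N_H = |H| and
N_R = Σ_{j∈H} |r_j|^p is

    step(i) = +|r_i|^p / N_R   if i ∈ H
              −1/(N − N_H)     otherwise,

so the profile always ends at zero and ES ∈ [−1, 1]. ES is the value at the
first position of maximal |value|; the first-position rule plus a 1e−12
tie slack makes the peak deterministic even when two excursions tie exactly
(where float rounding would otherwise pick a side arbitrarily). The weight
exponent defaults to p = 1; p = 0 reduces the statistic to the classical
signed two-sample Kolmogorov–Smirnov statistic, which the test suite checks
against a rational-arithmetic oracle.

The null permutes the score vector uniformly over the fixed accession order —
equivalently, shuffles membership over the sorted scores — which is how the
implementation vectorizes it. Each term draws from its own sub-seed
(seed + CRC32 of the term name, mod 2³¹), so adding or removing one term
never changes another term's null, and the RNG is consumed only after
canonical ranking so input row order cannot perturb draws.

NES and p-values use the same-sign convention: with S the non-zero null ES of
the observed sign, NES = ES / mean|S| and nominal p = (1 + #{|e| ≥ |ES|}) /
(1 + |S|). The +1 pseudo-count keeps finite-permutation p-values strictly
positive (minimum 1/(n_perm+1)). An empty same-sign null is a warned
degenerate case (NES = NaN, p = 1), not an error. The FDR q of a term is the
ratio of the same-sign pooled-null tail fraction to the same-sign observed
tail fraction at |NES|, clipped to [0, 1], followed by the usual monotone
cleanup: each term's q becomes the minimum over itself and all
weaker-or-equal same-sign terms, so q never increases with |NES|. Both an
adjusted nominal p (BH across terms) and the permutation q are reported,
since they answer slightly different questions.

Leading edge: for positive ES, the term's proteins at or before the peak;
for negative ES, at or after it. The negative branch is the mirror-image
convention — the core of a depletion signal sits at the bottom of the list —
and is documented here because only the positive case is ever described in
the GSEA literature's one-sentence definitions.

## Scores and occupancy

Differential expression per protein: log2(mean(treat)/mean(ctrl)) and a
pooled-variance two-sample t-test (|x|+|y|−2 df). Zero pooled variance with
equal means is a warned t = 0, p = 1; with different means it is an error —
a noise-free difference has no finite t and silently returning infinity
would poison downstream ranking. Missing intensities are absent, not zero;
proteins with fewer than two observed replicates per group are skipped and
reported. The default PSEA score is sign(log2FC)·(−log10 p), which keeps
direction and significance in one number; the raw fold change is available
as an alternative. The default list gate for SEA input is adjusted p < 0.05,
optionally combined with |log2FC| > 0.6.

Occupancy normalization follows three steps: per-channel total scaling
(removing loading/labelling differences), division by the summed normalized
intensity of the same protein's unmodified peptides (cancelling protein-level
abundance change), then per-condition means relative to the control
condition. The two invariances this buys — per-channel scaling and
per-protein abundance scaling — are asserted on randomized tables. A modified
peptide whose protein has no unmodified peptide has no within-protein
reference and is excluded with a report rather than silently normalized
against nothing.

## Export

`sea2mass`/`psea2mass` select terms with adjusted p below α (default 0.05;
the permutation q is selectable), rank PSEA terms by |NES| before truncating
to the top k (default 5), and map keywords through the vocabulary to exact
modifications, deduplicated by name. Keywords without vocabulary entries
(umbrella terms with no residue-level children in the vocabulary at hand)
are reported as unmatched instead of dropped silently. Output dialects: a
TSV and a minimal XML with one element per modification (name, monoisotopic
mass delta, site residues, position class); a modification without a defined
monoisotopic mass cannot be emitted as XML and raises.

## Synthetic study conditions

The generator emulates the real inputs' shape with planted truth. Defaults,
chosen once as the package's study conditions: 500 proteins, 8 PTM terms
drawn from common phospho/acetyl/ubiquitin/methyl keywords, per-term
annotation prevalence 0.3, Gaussian scores with sd 1.0, planted mean shift
δ = 3 on the enriched term's members, organism "Homo sapiens (Human)".
A t(3 df) score option exists for heavy-tail robustness checks. Expression
tables plant log2FC = 1 on enriched members with optional multiplicative
log2-normal noise; peptide tables plant a treated/control occupancy ratio
(default 0.5) under protein-level abundance changes that the normalization
must cancel.

What the generator does not emulate: correlated protein abundances,
missing-value structure, isotopic-label impurities, peptide identification
error, or annotation bias between organisms. Passing tests therefore
demonstrate the statistics' correctness and calibration under clean
exchangeable noise, not performance on any particular instrument's output.

## Verification sizes and numerics

The test suite checks the hypergeometric tail against exact rational
enumeration on the complete (N, K, n, m) grid for N ≤ 25, and the running-sum
ES against exact rational summation exhaustively for all member subsets at
list lengths up to 8 plus random subsets at 9–12 (integer scores keep the
oracle exact). Null calibration uses 500 synthetic null lists at 200
permutations (the minimum attainable nominal p, 1/201, resolves the 0.05
threshold comfortably); planted recovery uses 100 replicates at δ = 3,
noise 1, 200 permutations; t-test null uniformity uses 2000 3-vs-3
simulations. All simulations are seeded; hypothesis-based property tests run
derandomized. The acceptance script mirrors these computations at a slightly
reduced list count (200 null lists) and derives every stream from its `--seed`.

## Known limitations

* Enrichment can only ever surface PTMs that are annotated in the source
  database; sparsely annotated modification classes are invisible.
* The FT-note match is exact and case-sensitive; renamed vocabulary entries
  silently stop matching until the database is rebuilt with the matching
  vocabulary release.
* Phenotype-label permutation (the other GSEA null) is not implemented; the
  null is score permutation only.
* The export emits modification lists, not complete search-engine parameter
  files; residue/position strings pass through verbatim for the engine to
  interpret.
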