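"""Protein Set Enrichment Analysis (PSEA).

GSEA-style enrichment over a score-ranked protein list: a weighted,
signed Kolmogorov–Smirnov running sum is walked from the top to the bottom of
the list.  At each position the sum increases by |r_i|^p / N_R when the
protein carries the term (N_R being the summed weighted scores of the term's
proteins in the list) and decreases by 1/(N - N_H) otherwise, so the profile
returns to zero at the end of the list.  The enrichment score (ES) is the
value at the first position of maximal absolute deviation.

Significance comes from uniformly permuting the score vector over the fixed
accession order (equivalently, shuffling term membership over the sorted
score vector).  Normalized enrichment scores (NES) divide each ES by the mean
absolute same-sign null ES; the FDR q-value compares each |NES| against the
pooled same-sign null NES, with a monotone cleanup so q never increases with
|NES| within a sign.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .annotation import AnnotationDatabase, filter_by_organism
from .sea import adjust_pvalues
from .vocabulary import _open_text

__all__ = [
    "RankedList",
    "RunningProfile",
    "PSEAResult",
    "PSEAReport",
    "DegenerateStatisticWarning",
    "rank_proteins",
    "enrichment_score",
    "permutation_null",
    "nes_and_pvalues",
    "compute_fdr",
    "leading_edge",
    "run_psea",
    "read_scored_list",
]


class DegenerateStatisticWarning(UserWarning):
    """A permutation summary was degenerate (empty same-sign null, zero ES, …)."""


@dataclass
class RankedList:
    """Proteins sorted by descending score; ties broken by accession ascending."""

    accessions: list[str]
    scores: np.ndarray
    provenance: str = ""
    duplicates: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.accessions)

    def positions(self) -> dict[str, int]:
        return {acc: i for i, acc in enumerate(self.accessions)}


@dataclass
class RunningProfile:
    values: np.ndarray  # running-sum value after each list position
    peak_index: int     # first 0-based position attaining max |value|
    es: float           # signed value at the peak

    def to_frame(self, ranked: RankedList, members: set[str]) -> pd.DataFrame:
        """Per-position table behind running-score plots."""
        return pd.DataFrame(
            {
                "position": np.arange(1, len(ranked) + 1),
                "accession": ranked.accessions,
                "score": ranked.scores,
                "in_set": [acc in members for acc in ranked.accessions],
                "running": self.values,
            }
        )


@dataclass(frozen=True)
class PSEAResult:
    term: str
    set_size: int
    K: int
    es: float
    nes: float
    nominal_p: float
    adj_pvalue: float
    fdr_q: float
    leading_edge: tuple[str, ...]


@dataclass
class PSEAReport:
    results: list[PSEAResult]
    unmapped: list[str]
    skipped: dict[str, str]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "set_size": r.set_size,
                    "K": r.K,
                    "es": r.es,
                    "nes": r.nes,
                    "nominal_p": r.nominal_p,
                    "adj_pvalue": r.adj_pvalue,
                    "fdr_q": r.fdr_q,
                    "leading_edge": ",".join(r.leading_edge),
                }
                for r in self.results
            ],
            columns=[
                "term", "set_size", "K", "es", "nes", "nominal_p",
                "adj_pvalue", "fdr_q", "leading_edge",
            ],
        )


def rank_proteins(scored: Iterable[tuple[str, float]]) -> RankedList:
    """Build a :class:`RankedList` from (accession, score) pairs.

    Duplicate accessions collapse to the score of largest magnitude (reported
    in ``duplicates``); non-finite scores are errors.
    """
    best: dict[str, float] = {}
    duplicates: dict[str, float] = {}
    for acc, score in scored:
        score = float(score)
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for accession {acc!r}")
        if acc in best:
            duplicates[acc] = score if abs(score) > abs(best[acc]) else best[acc]
            if abs(score) > abs(best[acc]):
                best[acc] = score
        else:
            best[acc] = score
    items = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList(
        accessions=[acc for acc, _ in items],
        scores=np.array([s for _, s in items], dtype=float),
        duplicates=duplicates,
    )


def _hit_indicator(ranked: RankedList, members: set[str]) -> np.ndarray:
    return np.fromiter(
        (acc in members for acc in ranked.accessions), dtype=bool, count=len(ranked)
    )


def _es_from_indicators(
    weights: np.ndarray, indicators: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized running sums for a (M, N) boolean indicator matrix.

    Returns (cumulative profiles, first peak indices, signed ES values).
    """
    ind = np.atleast_2d(indicators)
    n_list = ind.shape[1]
    n_hits = ind.sum(axis=1)
    if np.any(n_hits == 0):
        raise ValueError("term absent from list")
    if np.any(n_hits == n_list):
        raise ValueError("set equals list")
    n_r = ind @ weights
    if np.any(n_r == 0):
        raise ValueError(
            "all in-set scores are zero under the chosen weight exponent; "
            "the weighted running sum is undefined"
        )
    miss_step = -1.0 / (n_list - n_hits)
    inc = np.where(ind, weights[None, :] / n_r[:, None], miss_step[:, None])
    profiles = np.cumsum(inc, axis=1)
    # first position attaining the max |value|; the 1e-12 slack keeps exact
    # ties (which float rounding would otherwise break arbitrarily) at the
    # earliest position
    absprof = np.abs(profiles)
    peaks = np.argmax(absprof >= absprof.max(axis=1)[:, None] - 1e-12, axis=1)
    es = profiles[np.arange(ind.shape[0]), peaks]
    return profiles, peaks, es


def enrichment_score(
    ranked: RankedList, members: set[str], weight_p: float = 1.0
) -> RunningProfile:
    """Weighted KS running sum of ``members`` along the ranked list."""
    if weight_p < 0:
        raise ValueError("weight_p must be non-negative")
    ind = _hit_indicator(ranked, members)
    weights = np.abs(ranked.scores) ** weight_p
    profiles, peaks, es = _es_from_indicators(weights, ind[None, :])
    return RunningProfile(values=profiles[0], peak_index=int(peaks[0]), es=float(es[0]))


def _null_memberships(
    ranked: RankedList, members: set[str], n_perm: int, seed: int
) -> np.ndarray:
    """Uniformly shuffled membership indicators, (n_perm, N) boolean."""
    rng = np.random.default_rng(seed)
    ind = _hit_indicator(ranked, members)
    return rng.permuted(np.tile(ind, (n_perm, 1)), axis=1)


def permutation_null(
    ranked: RankedList,
    members: set[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null ES values from uniform score permutations (reproducible from seed)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    null_ind = _null_memberships(ranked, members, n_perm, seed)
    weights = np.abs(ranked.scores) ** weight_p
    _, _, es = _es_from_indicators(weights, null_ind)
    return es


def nes_and_pvalues(es: float, null_es: Sequence[float]) -> tuple[float, float]:
    """Same-sign normalized ES and permutation p-value with a +1 pseudo-count."""
    null = np.asarray(null_es, dtype=float)
    if null.size == 0:
        raise ValueError("null_es must be non-empty")
    if es == 0:
        warnings.warn("ES is exactly zero; NES=0, p=1", DegenerateStatisticWarning)
        return 0.0, 1.0
    same = null[(np.sign(null) == np.sign(es)) & (null != 0)]
    if same.size == 0:
        warnings.warn(
            "no same-sign permutation ES values; NES undefined (NaN), p=1",
            DegenerateStatisticWarning,
        )
        return float("nan"), 1.0
    nes = es / np.mean(np.abs(same))
    nominal_p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
    return float(nes), float(nominal_p)


def _normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Turn a term's null ES sample into null NES, sign by sign."""
    out = np.full(null_es.shape, np.nan)
    pos = null_es > 0
    neg = null_es < 0
    if pos.any():
        out[pos] = null_es[pos] / np.mean(null_es[pos])
    if neg.any():
        out[neg] = null_es[neg] / np.mean(np.abs(null_es[neg]))
    out[null_es == 0] = 0.0
    return out


def compute_fdr(
    observed_nes: Sequence[float], null_nes_pool: Sequence[float]
) -> list[float]:
    """Permutation FDR q per term from the pooled null NES distribution.

    q = [same-sign pooled-null fraction with |NES| >= |nes*|]
        / [same-sign observed fraction with |NES| >= |nes*|], clipped to [0, 1],
    followed by a monotone cleanup so q is non-increasing in |nes*| per sign.
    """
    obs = np.asarray(observed_nes, dtype=float)
    pool = np.asarray(null_nes_pool, dtype=float)
    pool = pool[np.isfinite(pool)]
    q = np.ones(obs.size)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes) or nes == 0:
            warnings.warn(
                "degenerate NES in FDR computation; q=1", DegenerateStatisticWarning
            )
            continue
        sign = np.sign(nes)
        null_same = pool[np.sign(pool) == sign]
        obs_same = obs[np.isfinite(obs) & (np.sign(obs) == sign)]
        if null_same.size == 0:
            warnings.warn(
                "empty same-sign null pool; q=1", DegenerateStatisticWarning
            )
            continue
        num = np.mean(np.abs(null_same) >= abs(nes))
        den = np.mean(np.abs(obs_same) >= abs(nes))
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # monotone cleanup: within each sign, a stronger |NES| never gets a larger q
    for sign in (1.0, -1.0):
        idx = [i for i in range(obs.size)
               if np.isfinite(obs[i]) and np.sign(obs[i]) == sign]
        idx.sort(key=lambda i: abs(obs[i]))  # weakest first
        running = 1.0
        for i in idx:
            running = min(running, q[i])
            q[i] = running
    return [float(v) for v in q]


def leading_edge(
    ranked: RankedList, members: set[str], profile: RunningProfile
) -> list[str]:
    """The term's proteins up to (positive ES) or from (negative ES) the peak.

    For ES > 0 these are the members at positions at or before the running-sum
    peak; for ES < 0, at or after it.  List order is preserved.
    """
    if profile.es > 0:
        span = ranked.accessions[: profile.peak_index + 1]
    elif profile.es < 0:
        span = ranked.accessions[profile.peak_index:]
    else:
        return []
    return [acc for acc in span if acc in members]


def _term_seed(seed: int, term: str) -> int:
    """Stable per-term sub-seed: adding/removing one term never perturbs another."""
    return (int(seed) + zlib.crc32(term.encode())) % (2**31)


def run_psea(
    db: AnnotationDatabase,
    scored_list: Iterable[tuple[str, float]],
    organism: str | None = None,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_population_count: int = 5,
    adjust_method: str = "BH",
) -> PSEAReport:
    """Run PSEA for every analyzable PTM term against a scored protein list.

    Terms need a population count K >= ``min_population_count`` and a listed
    membership strictly between 0 and the list size.  Results are sorted by
    |NES| descending.  Fully reproducible from ``seed``.
    """
    if organism:
        db = filter_by_organism(db, organism)
    unmapped: list[str] = []
    pairs = []
    for acc, score in scored_list:
        primary = db.resolve(acc)
        if primary is None:
            unmapped.append(acc)
        else:
            pairs.append((primary, score))
    ranked = rank_proteins(pairs)
    if len(ranked) < 2:
        raise ValueError(
            f"scored list maps only {len(ranked)} protein(s) into the database; "
            "need at least 2"
        )
    listed = set(ranked.accessions)
    weights = np.abs(ranked.scores) ** weight_p

    skipped: dict[str, str] = {}
    terms: list[tuple[str, set[str], int]] = []
    for term in sorted(db.term_index):
        population = db.term_index[term]
        K = len(population)
        members = population & listed
        if K < min_population_count:
            skipped[term] = f"population count {K} < {min_population_count}"
        elif not members:
            skipped[term] = "term absent from list"
        elif len(members) == len(ranked):
            skipped[term] = "term members equal the whole list"
            warnings.warn(
                f"term {term!r} covers the entire list; excluded",
                DegenerateStatisticWarning,
            )
        else:
            terms.append((term, members, K))
    if not terms:
        raise ValueError(
            f"no analyzable term: {len(db.term_index)} terms in population, "
            f"{len(skipped)} skipped, list size {len(ranked)}"
        )

    records = []
    all_null_nes: list[np.ndarray] = []
    for term, members, K in terms:
        ind = _hit_indicator(ranked, members)
        profiles, peaks, es_arr = _es_from_indicators(weights, ind[None, :])
        profile = RunningProfile(
            values=profiles[0], peak_index=int(peaks[0]), es=float(es_arr[0])
        )
        null_ind = _null_memberships(ranked, members, n_perm, _term_seed(seed, term))
        _, _, null_es = _es_from_indicators(weights, null_ind)
        nes, nominal_p = nes_and_pvalues(profile.es, null_es)
        all_null_nes.append(_normalize_null(null_es))
        records.append(
            {
                "term": term,
                "set_size": len(members),
                "K": K,
                "es": profile.es,
                "nes": nes,
                "nominal_p": nominal_p,
                "leading_edge": tuple(leading_edge(ranked, members, profile)),
            }
        )
    adj = adjust_pvalues([r["nominal_p"] for r in records], adjust_method)
    fdr = compute_fdr(
        [r["nes"] for r in records], np.concatenate(all_null_nes)
    )
    results = [
        PSEAResult(adj_pvalue=a, fdr_q=q, **rec)
        for rec, a, q in zip(records, adj, fdr)
    ]
    results.sort(key=lambda r: (-(abs(r.nes) if np.isfinite(r.nes) else -1.0), r.term))
    return PSEAReport(
        results=results,
        unmapped=sorted(set(unmapped)),
        skipped=skipped,
        seed=seed,
    )


def read_scored_list(source: str | Path | TextIO) -> list[tuple[str, float]]:
    """Read a two-column (accession, score) TSV; optional header, '#' comments."""
    stream = _open_text(source)
    out: list[tuple[str, float]] = []
    for i, line in enumerate(stream):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"line {i + 1}: expected two columns, got {line!r}")
        try:
            score = float(parts[1])
        except ValueError:
            if i == 0:  # header row
                continue
            raise ValueError(f"line {i + 1}: score {parts[1]!r} is not numeric")
        out.append((parts[0], score))
    return out
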