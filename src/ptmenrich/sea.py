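"""Singular enrichment analysis (SEA): hypergeometric over-representation.

Given a population of N annotated proteins of which K carry a PTM term, and a
query list of n proteins of which m carry the term, the over-representation
p-value is the upper tail of the hypergeometric distribution,

    p = sum_{x=m}^{min(K,n)} C(K,x) C(N-K, n-x) / C(N,n),

computed in survival-function form for numerical stability.  One-sided
over-representation only; the test is conservative on the discrete support.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationDatabase
from .vocabulary import _open_text

__all__ = [
    "SEAResult",
    "SEAReport",
    "hypergeom_upper_pvalue",
    "adjust_pvalues",
    "run_sea",
    "read_protein_list",
]

_ADJUST_METHODS = {
    "BH": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "none": None,
}


@dataclass(frozen=True)
class SEAResult:
    term: str
    m: int
    n: int
    K: int
    N: int
    pvalue: float
    adj_pvalue: float

    @property
    def fold_enrichment(self) -> float:
        return (self.m / self.n) / (self.K / self.N)


@dataclass
class SEAReport:
    results: list[SEAResult]
    unmapped: list[str]
    n_mapped: int
    population_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "m": r.m,
                    "n": r.n,
                    "K": r.K,
                    "N": r.N,
                    "fold_enrichment": r.fold_enrichment,
                    "pvalue": r.pvalue,
                    "adj_pvalue": r.adj_pvalue,
                }
                for r in self.results
            ],
            columns=["term", "m", "n", "K", "N", "fold_enrichment", "pvalue", "adj_pvalue"],
        )

    def to_lollipop_frame(self) -> pd.DataFrame:
        """Long table behind the usual lollipop rendering of enrichment results."""
        return pd.DataFrame(
            {
                "term": [r.term for r in self.results],
                "neg_log10_adj_pvalue": [-np.log10(r.adj_pvalue) for r in self.results],
                "m": [r.m for r in self.results],
            }
        )


def hypergeom_upper_pvalue(N: int, K: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric P(X >= m) for X ~ Hypergeom(N, K, n)."""
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= m <= hi:
        raise ValueError(
            f"require max(0, n+K-N)={lo} <= m <= min(K, n)={hi}, got m={m}"
        )
    return float(min(1.0, hypergeom.sf(m - 1, N, K, n)))


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment; output order matches input order."""
    if method not in _ADJUST_METHODS:
        raise ValueError(
            f"unknown adjustment method {method!r}; "
            f"valid methods: {sorted(_ADJUST_METHODS)}"
        )
    arr = np.asarray(pvals, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none" or arr.size == 0:
        return [float(p) for p in arr]
    adjusted = multipletests(arr, method=_ADJUST_METHODS[method])[1]
    return [float(min(1.0, p)) for p in adjusted]


def run_sea(
    db: AnnotationDatabase,
    protein_list: Iterable[str],
    min_population_count: int = 5,
    adjust_method: str = "BH",
) -> SEAReport:
    """Test each PTM term for over-representation in an unranked protein list.

    The population is the database passed in (filter by organism upstream to
    scope it, or pass the full build / a detected-proteome background).  Terms
    with population count K below ``min_population_count`` or without any
    listed protein are not reported; the adjustment runs across exactly the
    reported terms.
    """
    if min_population_count < 1:
        raise ValueError("min_population_count must be >= 1")
    mapped: set[str] = set()
    unmapped: list[str] = []
    for acc in protein_list:
        primary = db.resolve(acc)
        if primary is None:
            unmapped.append(acc)
        else:
            mapped.add(primary)
    if not mapped:
        raise ValueError("none of the listed accessions map into the database")
    N = len(db.proteins)
    n = len(mapped)
    rows: list[tuple[str, int, int]] = []
    for term, members in db.term_index.items():
        K = len(members)
        if K < min_population_count:
            continue
        m = len(mapped & members)
        if m >= 1:
            rows.append((term, m, K))
    pvals = [hypergeom_upper_pvalue(N, K, n, m) for _, m, K in rows]
    order = sorted(range(len(rows)), key=lambda i: (pvals[i], rows[i][0]))
    adj = adjust_pvalues(pvals, adjust_method)
    results = [
        SEAResult(term=rows[i][0], m=rows[i][1], n=n, K=rows[i][2], N=N,
                  pvalue=pvals[i], adj_pvalue=adj[i])
        for i in order
    ]
    return SEAReport(results=results, unmapped=sorted(set(unmapped)),
                     n_mapped=n, population_size=N)


def read_protein_list(source: str | Path | TextIO) -> list[str]:
    """Read a plain-text accession list, one per line, '#' comments allowed."""
    stream = _open_text(source)
    out: list[str] = []
    for line in stream:
        line = re.sub(r"#.*", "", line).strip()
        if line:
            out.append(line)
    return out
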