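"""Protein-level ranking scores and modified-peptide occupancy normalization.

Differential expression between treated and control replicate intensities is
summarized by log2(mean(treat)/mean(ctrl)) and an equal-variance two-sample
t-test; the default PSEA ranking score is sign(log2FC) * (-log10 p).

Modified-peptide monitoring normalizes in two steps: each peptide intensity
is divided by its channel total (removing per-channel loading differences),
then by the summed normalized intensity of the same protein's unmodified
peptides (cancelling protein-level abundance changes), and finally each
condition's mean is expressed relative to the control condition.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log2_fold_change",
    "equal_variance_ttest",
    "protein_score",
    "differential_expression",
    "normalize_modified_peptides",
]


def log2_fold_change(
    treat_values: Sequence[float], ctrl_values: Sequence[float]
) -> float:
    """log2 of the ratio of group means (treatment over control)."""
    treat = np.asarray(treat_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if treat.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    if (treat < 0).any() or (ctrl < 0).any():
        raise ValueError("intensities must be non-negative")
    ctrl_mean = ctrl.mean()
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    return float(np.log2(treat.mean() / ctrl_mean))


def equal_variance_ttest(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance Student t-test, two-sided, |x|+|y|-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            warnings.warn("zero pooled variance with equal means; t=0, p=1")
            return 0.0, 1.0
        raise ValueError(
            "zero pooled variance with different means; t undefined"
        )
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def protein_score(lfc: float, pvalue: float, kind: str = "signed_logp") -> float:
    """Ranking score for PSEA.

    kinds: "signed_logp" (default) = sign(lfc) * (-log10 p); "lfc" = the fold
    change itself.  ``pvalue`` must be in (0, 1]; floor p upstream if an
    adjustment produced exact zeros.
    """
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    if kind == "lfc":
        return float(lfc)
    if kind != "signed_logp":
        raise ValueError(f"unknown score kind {kind!r}")
    return float(np.sign(lfc) * -math.log10(pvalue))


def differential_expression(
    table: pd.DataFrame,
    treat_columns: Sequence[str],
    ctrl_columns: Sequence[str],
    adjust_method: str = "BH",
    score_kind: str = "signed_logp",
) -> pd.DataFrame:
    """Per-protein log2FC, t-test p, adjusted p and PSEA score for a wide table.

    ``table`` is indexed by accession with one column per sample.  Missing
    intensities are treated as absent; proteins with fewer than 2 observed
    replicates in either group are skipped and flagged in the ``skipped``
    attribute of the result.
    """
    from .sea import adjust_pvalues

    rows = []
    skipped: list[str] = []
    for acc, row in table.iterrows():
        treat = row[list(treat_columns)].dropna().to_numpy(dtype=float)
        ctrl = row[list(ctrl_columns)].dropna().to_numpy(dtype=float)
        if treat.size < 2 or ctrl.size < 2:
            skipped.append(str(acc))
            continue
        lfc = log2_fold_change(treat, ctrl)
        t, p = equal_variance_ttest(treat, ctrl)
        rows.append({"accession": acc, "log2fc": lfc, "t": t, "pvalue": p})
    out = pd.DataFrame(rows, columns=["accession", "log2fc", "t", "pvalue"])
    if len(out):
        out["adj_pvalue"] = adjust_pvalues(out["pvalue"].tolist(), adjust_method)
        floor = np.nextafter(0.0, 1.0)
        out["score"] = [
            protein_score(l, max(p, floor), kind=score_kind)
            for l, p in zip(out["log2fc"], out["pvalue"])
        ]
    else:
        out["adj_pvalue"] = []
        out["score"] = []
    out.attrs["skipped"] = skipped
    return out


def normalize_modified_peptides(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    control: str,
) -> pd.DataFrame:
    """Occupancy ratios of modified peptides relative to the control condition.

    ``table`` needs columns ``peptide``, ``protein``, ``modifications`` (empty
    string / NaN marks an unmodified peptide) plus one intensity column per
    channel named in ``groups`` (channel → condition).  Returns a long table
    (peptide, protein, condition, ratio) for modified peptides; the ratio for
    the control condition is 1 by construction.  Modified peptides whose
    protein has no unmodified peptide are excluded and listed in the
    ``excluded`` attribute.
    """
    channels = list(groups)
    conditions = sorted(set(groups.values()))
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not present in groups")
    inten = table[channels].to_numpy(dtype=float)
    totals = inten.sum(axis=0)
    if (totals == 0).any():
        zero = [channels[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"zero total intensity in channel(s): {zero}")
    norm = inten / totals  # step 1: per-channel normalization

    mods = table["modifications"].fillna("").astype(str).str.strip()
    is_mod = mods != ""
    # step 2: divide by summed normalized intensity of the protein's
    # unmodified peptides, per channel
    unmod_sum: dict[str, np.ndarray] = {}
    for prot, idx in table.groupby("protein").indices.items():
        idx = np.asarray(idx)
        unmod_idx = idx[~is_mod.to_numpy()[idx]]
        unmod_sum[prot] = norm[unmod_idx].sum(axis=0)

    rows = []
    excluded: list[str] = []
    cond_cols = {
        cond: [i for i, ch in enumerate(channels) if groups[ch] == cond]
        for cond in conditions
    }
    for i in np.flatnonzero(is_mod.to_numpy()):
        prot = table["protein"].iat[i]
        denom = unmod_sum[prot]
        if not (denom > 0).all():
            excluded.append(str(table["peptide"].iat[i]))
            continue
        r = norm[i] / denom
        ctrl_mean = r[cond_cols[control]].mean()
        for cond in conditions:
            rows.append(
                {
                    "peptide": table["peptide"].iat[i],
                    "protein": prot,
                    "condition": cond,
                    "ratio": r[cond_cols[cond]].mean() / ctrl_mean,
                }
            )
    out = pd.DataFrame(rows, columns=["peptide", "protein", "condition", "ratio"])
    out.attrs["excluded"] = excluded
    return out
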