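"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the shape of the real inputs — a Swiss-Prot-dialect
flat file of annotated proteins, a score-ranked protein list from a
treated-vs-control comparison, and replicate intensity tables — with known
truth planted, so enrichment recovery, calibration and normalization can be
checked without downloads.  Scores are Gaussian by default (a t with 3 df is
available for heavy-tail robustness checks); every generator is a pure
function of its seed and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import AnnotationDatabase, RawRecord, build_database
from .vocabulary import Vocabulary

__all__ = [
    "SimulationConfig",
    "simulate_database",
    "render_flatfile",
    "simulate_scored_list",
    "simulate_expression_tables",
    "write_fixture_dir",
    "packaged_data_path",
]

_DEFAULT_TERMS = [
    "Phosphothreonine",
    "Phosphoserine",
    "Phosphotyrosine",
    "N6-acetyllysine",
    "N-acetylalanine",
    "N-acetylmethionine",
    "Ubl conjugation",
    "Methylation",
]


def packaged_data_path(name: str) -> Path:
    """Path to a packaged text fixture (ptmlist, keyword list, flat file)."""
    return Path(resources.files("ptmenrich.data") / name)  # type: ignore[arg-type]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs."""

    n_proteins: int = 500
    terms: list[str] = field(default_factory=lambda: list(_DEFAULT_TERMS))
    prevalence: float = 0.3          # per-term annotation probability
    enriched_term: str = "Phosphothreonine"
    effect_size: float = 3.0         # mean score shift for enriched-term members
    noise: float = 1.0               # score standard deviation
    score_distribution: str = "normal"  # or "t3" for heavy tails
    organism: str = "Homo sapiens (Human)"
    seed: int = 0
    # expression / peptide table conditions
    n_expr_proteins: int = 20
    planted_lfc: float = 1.0
    expr_noise_sd: float = 0.0       # multiplicative log2-normal noise
    planted_occupancy: float = 0.5   # treated/control occupancy ratio

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be >= 10")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _accession(i: int) -> str:
    return f"P{i + 1:05d}"


def _records(cfg: SimulationConfig) -> list[RawRecord]:
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_proteins):
        carried = {
            term for term in cfg.terms if rng.random() < cfg.prevalence
        }
        records.append(
            RawRecord(
                accessions=[_accession(i)],
                organism=cfg.organism,
                keywords=carried | {"Reference proteome"},
                features=[],
            )
        )
    return records


def simulate_database(
    cfg: SimulationConfig,
) -> tuple[AnnotationDatabase, str]:
    """A database with independently Bernoulli-planted term annotations.

    Returns the in-memory database and a Swiss-Prot-dialect text rendering
    that parses back to an equal database.
    """
    records = _records(cfg)
    db = build_database(
        records,
        Vocabulary(),
        ptm_keyword_universe=set(cfg.terms),
        source_name="synthetic",
        vocabulary_version="synthetic",
    )
    return db, render_flatfile(records)


def render_flatfile(records: list[RawRecord]) -> str:
    """Render raw records in the flat-file dialect the annotation parser reads."""
    chunks = []
    for i, rec in enumerate(records):
        lines = [
            f"ID   SYN{i + 1:04d}_SYNTH        Reviewed;         100 AA.",
            "AC   " + " ".join(f"{acc};" for acc in rec.accessions),
            f"OS   {rec.organism}.",
        ]
        keywords = sorted(rec.keywords)
        if keywords:
            # wrap at keyword boundaries so the per-line ';' split is safe
            line = "KW   "
            for j, kw in enumerate(keywords):
                token = kw + ("." if j == len(keywords) - 1 else ";")
                if len(line) + len(token) > 75 and line.strip() != "KW":
                    lines.append(line.rstrip())
                    line = "KW   "
                line += token + " "
            lines.append(line.rstrip())
        for key, note in rec.features:
            lines.append(f"FT   {key:<15} 1")
            if note:
                lines.append(f'FT                   /note="{note}"')
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def simulate_scored_list(
    db: AnnotationDatabase, cfg: SimulationConfig, seed: int | None = None
) -> tuple[list[tuple[str, float]], dict]:
    """Score every protein: enriched-term members get a +effect_size mean shift.

    Returns the scored list and a truth record (enriched term, member
    accessions, configuration).  ``seed`` defaults to ``cfg.seed``.
    """
    if cfg.enriched_term not in db.term_index and cfg.effect_size > 0:
        raise ValueError(
            f"enriched term {cfg.enriched_term!r} is absent from the database"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    accessions = sorted(db.proteins)
    members = db.term_index.get(cfg.enriched_term, set())
    n = len(accessions)
    if cfg.score_distribution == "normal":
        noise = rng.normal(0.0, cfg.noise, size=n)
    elif cfg.score_distribution == "t3":
        noise = rng.standard_t(3, size=n) * cfg.noise
    else:
        raise ValueError(f"unknown score distribution {cfg.score_distribution!r}")
    scores = noise + np.where(
        [acc in members for acc in accessions], cfg.effect_size, 0.0
    )
    truth = {
        "enriched_term": cfg.enriched_term,
        "members": sorted(members),
        "effect_size": cfg.effect_size,
        "noise": cfg.noise,
    }
    return list(zip(accessions, scores.tolist())), truth


def simulate_expression_tables(
    db: AnnotationDatabase, cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicate intensity tables with planted fold changes and occupancies.

    The expression table holds 3 control + 3 treated replicates per protein;
    enriched-term members carry log2FC = ``planted_lfc``, everything else 0,
    with optional multiplicative log2-normal noise.  The peptide table gives
    each protein three unmodified peptides and one modified peptide whose
    treated/control occupancy ratio is ``planted_occupancy``; protein-level
    abundance changes apply to all of a protein's peptides and therefore
    cancel in the occupancy normalization.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    accessions = sorted(db.proteins)[: cfg.n_expr_proteins]
    members = db.term_index.get(cfg.enriched_term, set())
    ctrl_cols = [f"ctrl_{i}" for i in range(1, 4)]
    treat_cols = [f"treat_{i}" for i in range(1, 4)]

    expr_rows = []
    lfc_truth = {}
    pep_rows = []
    occ_truth = {}
    channel_scale = {c: 1.0 for c in ctrl_cols} | {c: 1.0 for c in treat_cols}
    for acc in accessions:
        base = float(rng.uniform(1e5, 1e6))
        lfc = cfg.planted_lfc if acc in members else 0.0
        lfc_truth[acc] = lfc

        def noisy(value: float) -> float:
            if cfg.expr_noise_sd == 0:
                return value
            return value * float(2.0 ** rng.normal(0.0, cfg.expr_noise_sd))

        row = {"accession": acc}
        for c in ctrl_cols:
            row[c] = noisy(base)
        for c in treat_cols:
            row[c] = noisy(base * 2.0**lfc)
        expr_rows.append(row)

        # peptide table: protein abundance factor applies to every peptide,
        # the occupancy factor only to the modified one
        unmod_base = [base * f for f in (0.5, 0.3, 0.2)]
        mod_base = base * 0.1
        for j, ub in enumerate(unmod_base, start=1):
            pep = {"peptide": f"{acc}_u{j}", "protein": acc, "modifications": ""}
            for c in ctrl_cols:
                pep[c] = noisy(ub * channel_scale[c])
            for c in treat_cols:
                pep[c] = noisy(ub * 2.0**lfc * channel_scale[c])
            pep_rows.append(pep)
        pep = {
            "peptide": f"{acc}_m1",
            "protein": acc,
            "modifications": "O-phospho-L-threonine",
        }
        for c in ctrl_cols:
            pep[c] = noisy(mod_base * channel_scale[c])
        for c in treat_cols:
            pep[c] = noisy(
                mod_base * 2.0**lfc * cfg.planted_occupancy * channel_scale[c]
            )
        pep_rows.append(pep)
        occ_truth[f"{acc}_m1"] = cfg.planted_occupancy

    expr = pd.DataFrame(expr_rows).set_index("accession")
    peptides = pd.DataFrame(pep_rows)
    truth = {
        "log2fc": lfc_truth,
        "occupancy": occ_truth,
        "ctrl_columns": ctrl_cols,
        "treat_columns": treat_cols,
    }
    return expr, peptides, truth


def write_fixture_dir(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write all synthetic inputs (flat file, scores, tables, truth) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db, flatfile_text = simulate_database(cfg)
    scored, truth = simulate_scored_list(db, cfg)
    expr, peptides, expr_truth = simulate_expression_tables(db, cfg)

    paths = {
        "flatfile": outdir / "proteins.dat",
        "ptmlist": outdir / "ptmlist.txt",
        "keywords": outdir / "ptm_keywords.txt",
        "scores": outdir / "scores.tsv",
        "expression": outdir / "expression.tsv",
        "peptides": outdir / "peptides.tsv",
        "design": outdir / "design.yaml",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    paths["flatfile"].write_text(flatfile_text)
    paths["ptmlist"].write_text(packaged_data_path("ptmlist_fixture.txt").read_text())
    paths["keywords"].write_text(packaged_data_path("ptm_keywords.txt").read_text())
    with open(paths["scores"], "w") as fh:
        fh.write("accession\tscore\n")
        for acc, score in scored:
            fh.write(f"{acc}\t{score:.10g}\n")
    expr.to_csv(paths["expression"], sep="\t")
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    design = {
        "groups": {c: "control" for c in expr_truth["ctrl_columns"]}
        | {c: "treatment" for c in expr_truth["treat_columns"]},
        "control": "control",
    }
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(design, fh, sort_keys=False)
    with open(paths["truth"], "w") as fh:
        json.dump({**truth, **expr_truth}, fh, indent=1, sort_keys=True)
    cfg.to_yaml(paths["config"])
    return paths
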