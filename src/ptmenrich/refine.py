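"""Turn enriched PTM terms into an exact-modification list for a refined search.

Enriched keywords from SEA or PSEA are mapped through the controlled
vocabulary to the exact chemical modifications they group, producing a table
(or a minimal search-engine XML document) that can parametrize the variable
modifications of a second, refined database search.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .psea import PSEAResult
from .sea import SEAResult
from .vocabulary import Vocabulary, keyword_to_modifications

__all__ = [
    "ModificationRow",
    "ModificationExport",
    "sea2mass",
    "psea2mass",
    "write_modification_table",
    "read_modification_table",
]


@dataclass(frozen=True)
class ModificationRow:
    name: str
    keyword: str
    target: str
    position: str
    mono_mass_delta: float | None
    statistic: float
    rank: int


@dataclass
class ModificationExport:
    rows: list[ModificationRow] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    def names(self) -> list[str]:
        return [r.name for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "keyword": r.keyword,
                    "target": r.target,
                    "position": r.position,
                    "mono_mass_delta": r.mono_mass_delta,
                    "statistic": r.statistic,
                    "rank": r.rank,
                }
                for r in self.rows
            ],
            columns=[
                "name", "keyword", "target", "position",
                "mono_mass_delta", "statistic", "rank",
            ],
        )


def _export(
    selected: Sequence[tuple[str, float]], vocab: Vocabulary
) -> ModificationExport:
    """Map (keyword, statistic) pairs to unique modification rows."""
    export = ModificationExport()
    seen: set[str] = set()
    for rank, (keyword, stat) in enumerate(selected, start=1):
        entries, unmatched = keyword_to_modifications(vocab, [keyword])
        export.unmatched.extend(unmatched)
        for entry in entries:
            if entry.id in seen:
                continue
            seen.add(entry.id)
            export.rows.append(
                ModificationRow(
                    name=entry.id,
                    keyword=keyword,
                    target=entry.target,
                    position=entry.position,
                    mono_mass_delta=entry.mono_mass_delta,
                    statistic=stat,
                    rank=rank,
                )
            )
    export.rows.sort(key=lambda r: (r.statistic, r.name))
    return export


def sea2mass(
    results: Sequence[SEAResult],
    vocab: Vocabulary,
    alpha: float = 0.05,
    top_k: int | None = None,
) -> ModificationExport:
    """Exact modifications for SEA terms significant at ``alpha`` (adjusted p)."""
    if not results:
        raise ValueError("results must be non-empty")
    selected = [(r.term, r.adj_pvalue) for r in results if r.adj_pvalue < alpha]
    selected.sort(key=lambda ks: (ks[1], ks[0]))
    if top_k is not None:
        selected = selected[:top_k]
    if not selected:
        warnings.warn(f"no term significant at alpha={alpha}; export is empty")
    return _export(selected, vocab)


def psea2mass(
    results: Sequence[PSEAResult],
    vocab: Vocabulary,
    alpha: float = 0.05,
    top_k: int | None = 5,
) -> ModificationExport:
    """Exact modifications for PSEA terms significant at ``alpha`` (adjusted p).

    Terms are ranked by |NES| descending before the top-k truncation, matching
    how the strongest enriched modifications are carried into a refined search.
    """
    if not results:
        raise ValueError("results must be non-empty")
    passed = [r for r in results if r.adj_pvalue < alpha]
    passed.sort(key=lambda r: (-abs(r.nes), r.term))
    if top_k is not None:
        passed = passed[:top_k]
    if not passed:
        warnings.warn(f"no term significant at alpha={alpha}; export is empty")
    return _export([(r.term, r.adj_pvalue) for r in passed], vocab)


_TSV_COLUMNS = ["name", "keyword", "target", "position", "mono_mass_delta",
                "statistic", "rank"]


def write_modification_table(
    export: ModificationExport, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write the export as TSV or as a minimal search-engine modification XML."""
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for r in export.rows:
                mass = "" if r.mono_mass_delta is None else f"{r.mono_mass_delta:.6f}"
                fh.write(
                    "\t".join(
                        [r.name, r.keyword, r.target, r.position, mass,
                         f"{r.statistic:.6g}", str(r.rank)]
                    )
                    + "\n"
                )
        return
    if dialect != "maxquant-xml":
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'maxquant-xml'")
    if not export.rows:
        raise ValueError("maxquant-xml dialect requires a non-empty export")
    root = ET.Element("modifications")
    for r in export.rows:
        if r.mono_mass_delta is None:
            raise ValueError(
                f"modification {r.name!r} has no monoisotopic mass delta; "
                "cannot emit a search-engine entry"
            )
        ET.SubElement(
            root,
            "modification",
            attrib={
                "title": r.name,
                "delta_mass": f"{r.mono_mass_delta:.6f}",
                "site": r.target,
                "position": r.position or "Anywhere",
            },
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


def read_modification_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Round-trip reader for the two export dialects (used in verification)."""
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t")
    if dialect != "maxquant-xml":
        raise ValueError(f"unknown dialect {dialect!r}")
    root = ET.parse(path).getroot()
    rows = [
        {
            "title": el.get("title"),
            "delta_mass": float(el.get("delta_mass")),
            "site": el.get("site"),
            "position": el.get("position"),
        }
        for el in root.iter("modification")
    ]
    return pd.DataFrame(rows, columns=["title", "delta_mass", "site", "position"])
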