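"""Swiss-Prot flat-file parsing and the protein↔PTM-term annotation database.

Each reviewed protein record is reduced to its accessions (AC), organism
taxonomy name (OS), keywords (KW) and features (FT).  A protein's PTM-term
set is derived from two sources:

* KW keywords intersected with the PTM keyword universe (controlled-vocabulary
  keywords plus an optional supplementary PTM keyword list), and
* MOD_RES / CROSSLNK / LIPID features whose ``/note`` text, truncated at the
  first ``;``, exactly matches a controlled-vocabulary modification id — the
  feature then contributes that modification's parent keyword.

Proteins with an empty PTM-term set are retained: they count toward the
population size N of the enrichment tests.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

from .vocabulary import Vocabulary, _open_text

__all__ = [
    "RawRecord",
    "ProteinRecord",
    "AnnotationDatabase",
    "parse_flatfile_records",
    "build_database",
    "filter_by_organism",
    "term_frequencies",
    "save_database",
    "load_database",
    "canonicalize_accession",
]

_PTM_FEATURE_KEYS = {"MOD_RES", "CROSSLNK", "LIPID"}
_DB_FORMAT_VERSION = "ptmenrich-db/1"
# pre-2019 columnar FT dialect: feature key followed by two numeric columns
_OLD_FT_RE = re.compile(r"^\S+\s+[<>?]?\d+\s+[<>?]?\d+(\s|$)")


@dataclass
class RawRecord:
    """One flat-file record reduced to the fields the database build uses."""

    accessions: list[str]
    organism: str
    keywords: set[str]
    features: list[tuple[str, str]]  # (feature_key, note text or "")

    @property
    def primary_accession(self) -> str:
        return self.accessions[0]


@dataclass
class ProteinRecord:
    accession: str
    organism: str
    keywords: set[str] = field(default_factory=set)
    ptm_terms: set[str] = field(default_factory=set)
    secondary_accessions: list[str] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinRecord):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.organism == other.organism
            and self.keywords == other.keywords
            and self.ptm_terms == other.ptm_terms
            and self.secondary_accessions == other.secondary_accessions
        )


@dataclass
class AnnotationDatabase:
    """Bidirectional protein↔PTM-term index with organism scoping."""

    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    term_index: dict[str, set[str]] = field(default_factory=dict)
    organism_index: dict[str, set[str]] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def resolve(self, accession: str) -> str | None:
        """Resolve a user accession (isoform suffix, secondary AC) to a primary AC."""
        acc = canonicalize_accession(accession)
        if acc in self.proteins:
            return acc
        return self.aliases.get(acc)

    def equals(self, other: "AnnotationDatabase") -> bool:
        return (
            self.proteins == other.proteins
            and self.term_index == other.term_index
            and self.organism_index == other.organism_index
            and self.aliases == other.aliases
            and self.meta == other.meta
        )


def canonicalize_accession(accession: str) -> str:
    """Strip an isoform suffix ("P12345-2" → "P12345") and whitespace."""
    acc = accession.strip()
    head, sep, tail = acc.rpartition("-")
    if sep and tail.isdigit():
        return head
    return acc


def parse_flatfile_records(source: str | Path | TextIO) -> Iterator[RawRecord]:
    """Yield one :class:`RawRecord` per ``//``-terminated flat-file block.

    Only AC/OS/KW/FT lines are interpreted; all other line codes are skipped.
    Only the current FT dialect (location line + ``/note="…"`` qualifier
    continuations) is accepted; the pre-2019 columnar dialect is rejected.
    """
    stream = _open_text(source)
    ordinal = 0
    acc: list[str] = []
    os_parts: list[str] = []
    keywords: set[str] = set()
    features: list[tuple[str, str]] = []
    cur_key: str | None = None
    cur_note: str | None = None  # open /note text awaiting its closing quote
    in_record = False

    def close_feature() -> None:
        nonlocal cur_key, cur_note
        if cur_key is not None:
            features.append((cur_key, cur_note or ""))
        cur_key = None
        cur_note = None

    for line in stream:
        line = line.rstrip("\n")
        code = line[:2]
        if line.startswith("//"):
            close_feature()
            ordinal += 1
            if not acc:
                raise ValueError(f"record #{ordinal} has no AC line")
            yield RawRecord(
                accessions=acc,
                organism=" ".join(os_parts).rstrip("."),
                keywords=keywords,
                features=features,
            )
            acc, os_parts, keywords, features = [], [], set(), []
            in_record = False
            continue
        if not code.strip():
            continue
        in_record = True
        value = line[5:] if len(line) > 5 else ""
        if code == "AC":
            acc.extend(tok.strip() for tok in value.split(";") if tok.strip())
        elif code == "OS":
            os_parts.append(value.strip())
        elif code == "KW":
            for tok in value.split(";"):
                tok = tok.strip().rstrip(".").strip()
                if tok:
                    keywords.add(tok)
        elif code == "FT":
            if value[:1] != " ":  # new feature: key at the start of the value field
                close_feature()
                key = value.split()[0] if value.split() else ""
                rest = value[len(key):].strip()
                if _OLD_FT_RE.match(value):
                    raise ValueError(
                        "pre-2019 columnar FT dialect detected "
                        f"(record #{ordinal + 1}: {line!r}); "
                        "only the /note qualifier dialect is supported"
                    )
                cur_key = key
            else:
                qual = value.strip()
                if cur_note is not None:
                    # continuation of an open /note string
                    if qual.endswith('"'):
                        cur_note += " " + qual[:-1]
                        # note closed; keep feature open for further qualifiers
                        features.append((cur_key, cur_note))  # type: ignore[arg-type]
                        cur_key, cur_note = None, None
                    else:
                        cur_note += " " + qual
                elif qual.startswith('/note="') and cur_key is not None:
                    body = qual[len('/note="'):]
                    if body.endswith('"'):
                        features.append((cur_key, body[:-1]))  # type: ignore[arg-type]
                        cur_key, cur_note = None, None
                    else:
                        cur_note = body
    if in_record or acc or os_parts or keywords or features:
        raise ValueError(
            f"unterminated final record (#{ordinal + 1}): missing closing '//'"
        )


def build_database(
    records: Iterable[RawRecord],
    vocab: Vocabulary,
    ptm_keyword_universe: set[str] | None = None,
    source_name: str = "",
    vocabulary_version: str = "",
) -> AnnotationDatabase:
    """Compile parsed records into an :class:`AnnotationDatabase`.

    ``ptm_keyword_universe`` defaults to the vocabulary's keyword set; pass
    the union with a supplementary keyword list to include umbrella terms
    (e.g. "Phosphoprotein") that appear only on KW lines.
    """
    universe = set(ptm_keyword_universe) if ptm_keyword_universe is not None else vocab.keywords
    note_to_keyword = {
        e.id: e.keyword for e in vocab.entries if e.keyword
    }
    db = AnnotationDatabase(
        meta={
            "format": _DB_FORMAT_VERSION,
            "source": source_name,
            "vocabulary_version": vocabulary_version,
            "n_universe_keywords": len(universe),
        }
    )
    for rec in records:
        primary = rec.primary_accession
        terms = rec.keywords & universe
        for key, note in rec.features:
            if key in _PTM_FEATURE_KEYS:
                name = note.split(";", 1)[0].strip()
                kw = note_to_keyword.get(name)
                if kw:
                    terms.add(kw)
        db.proteins[primary] = ProteinRecord(
            accession=primary,
            organism=rec.organism,
            keywords=set(rec.keywords),
            ptm_terms=terms,
            secondary_accessions=list(rec.accessions[1:]),
        )
        for sec in rec.accessions[1:]:
            db.aliases[sec] = primary
        db.organism_index.setdefault(rec.organism, set()).add(primary)
        for term in terms:
            db.term_index.setdefault(term, set()).add(primary)
    return db


def filter_by_organism(db: AnnotationDatabase, taxon_name: str) -> AnnotationDatabase:
    """Restrict the database to organisms containing ``taxon_name`` (case-insensitive)."""
    if not taxon_name:
        raise ValueError("taxon_name must be non-empty")
    needle = taxon_name.lower()
    keep_orgs = {org for org in db.organism_index if needle in org.lower()}
    if not keep_orgs:
        raise ValueError(
            f"no proteins match organism {taxon_name!r}; "
            "check the taxonomy name against the database"
        )
    out = AnnotationDatabase(meta={**db.meta, "organism_filter": taxon_name})
    for org in keep_orgs:
        for acc in db.organism_index[org]:
            rec = db.proteins[acc]
            out.proteins[acc] = rec
            out.organism_index.setdefault(org, set()).add(acc)
            for sec in rec.secondary_accessions:
                out.aliases[sec] = acc
            for term in rec.ptm_terms:
                out.term_index.setdefault(term, set()).add(acc)
    return out


def term_frequencies(db: AnnotationDatabase) -> pd.DataFrame:
    """Per-term protein counts, descending by count, ties by term ascending."""
    rows = sorted(
        ((term, len(accs)) for term, accs in db.term_index.items()),
        key=lambda tc: (-tc[1], tc[0]),
    )
    return pd.DataFrame(rows, columns=["term", "count"])


def save_database(db: AnnotationDatabase, path: str | Path) -> None:
    """Serialize to a versioned, gzip-compressed JSON payload with a checksum."""
    payload = {
        "format": _DB_FORMAT_VERSION,
        "meta": db.meta,
        "proteins": {
            acc: {
                "organism": rec.organism,
                "keywords": sorted(rec.keywords),
                "ptm_terms": sorted(rec.ptm_terms),
                "secondary_accessions": rec.secondary_accessions,
            }
            for acc, rec in sorted(db.proteins.items())
        },
    }
    body = json.dumps(payload, sort_keys=True).encode()
    digest = hashlib.sha256(body).hexdigest()
    # mtime=0 keeps the gzip output byte-identical across runs
    with gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0) as fh:
        fh.write(json.dumps({"sha256": digest}).encode() + b"\n")
        fh.write(body)


def load_database(path: str | Path) -> AnnotationDatabase:
    try:
        with gzip.open(path, "rb") as fh:
            header = json.loads(fh.readline())
            body = fh.read()
    except (OSError, EOFError, json.JSONDecodeError, gzip.BadGzipFile) as exc:
        raise ValueError(f"corrupted database file {path}: {exc}") from exc
    if hashlib.sha256(body).hexdigest() != header.get("sha256"):
        raise ValueError(f"corrupted database file {path}: checksum mismatch")
    payload = json.loads(body)
    version = payload.get("format")
    if version != _DB_FORMAT_VERSION:
        raise ValueError(
            f"database format version mismatch: file has {version!r}, "
            f"this build reads {_DB_FORMAT_VERSION!r}"
        )
    db = AnnotationDatabase(meta=payload["meta"])
    for acc, rec in payload["proteins"].items():
        pr = ProteinRecord(
            accession=acc,
            organism=rec["organism"],
            keywords=set(rec["keywords"]),
            ptm_terms=set(rec["ptm_terms"]),
            secondary_accessions=list(rec["secondary_accessions"]),
        )
        db.proteins[acc] = pr
        db.organism_index.setdefault(pr.organism, set()).add(acc)
        for sec in pr.secondary_accessions:
            db.aliases[sec] = acc
        for term in pr.ptm_terms:
            db.term_index.setdefault(term, set()).add(acc)
    return db
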