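"""UniProt PTM controlled-vocabulary (ptmlist) parsing and keyword lookups.

The controlled vocabulary registers exact chemical modifications: each record
carries the modification name (ID), a feature key (MOD_RES / CROSSLNK / LIPID),
the target residue, a position class, monoisotopic and average mass deltas, and
the parent PTM keyword (KW) that groups residue-level modifications under a
protein-level annotation term (e.g. "Phosphothreonine" for
"O-phospho-L-threonine").

The dialect is line oriented: a two-letter code, three spaces, then the value;
a repeated code continues the previous value; records end with ``//``.  A free
text header before the first ``ID`` line is permitted and ignored.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "VocabularyEntry",
    "Vocabulary",
    "parse_ptm_vocabulary",
    "keyword_to_modifications",
    "serialize_vocabulary",
    "write_vocabulary_tsv",
    "read_keyword_list",
]

_FEATURE_KEYS = {"MOD_RES", "CROSSLNK", "LIPID"}


@dataclass(frozen=True)
class VocabularyEntry:
    """One controlled-vocabulary record (one exact modification)."""

    id: str
    accession: str = ""
    feature_key: str = "other"
    target: str = "Undefined"
    position: str = ""
    mono_mass_delta: float | None = None
    avg_mass_delta: float | None = None
    correction_formula: str = ""
    keyword: str = ""


@dataclass
class Vocabulary:
    """Ordered collection of vocabulary entries with id and keyword indexes."""

    entries: list[VocabularyEntry] = field(default_factory=list)
    by_id: dict[str, VocabularyEntry] = field(default_factory=dict)
    by_keyword: dict[str, list[VocabularyEntry]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keywords(self) -> set[str]:
        return set(self.by_keyword)

    @classmethod
    def from_entries(cls, entries: Iterable[VocabularyEntry]) -> "Vocabulary":
        vocab = cls()
        for entry in entries:
            if entry.id in vocab.by_id:
                raise ValueError(f"duplicate vocabulary ID {entry.id!r}")
            vocab.entries.append(entry)
            vocab.by_id[entry.id] = entry
            if entry.keyword:
                vocab.by_keyword.setdefault(entry.keyword, []).append(entry)
        return vocab


def _open_text(source: str | Path | TextIO) -> TextIO:
    """Open a path (plain or gzip) as text; pass file objects through.

    Bytes are decoded as UTF-8 with a Latin-1 fallback — historic UniProt
    releases mix the two encodings.
    """
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    opener = gzip.open if path.suffix == ".gz" else open
    raw = opener(path, "rb").read()  # type: ignore[call-overload]
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return io.StringIO(text)


def parse_ptm_vocabulary(source: str | Path | TextIO) -> Vocabulary:
    """Parse a ptmlist-dialect stream into a :class:`Vocabulary`.

    Unknown line codes are ignored; trailing periods on ID/TG/KW values are
    stripped; duplicate IDs, records without an ID, and unparseable mass
    values are errors.
    """
    stream = _open_text(source)
    fields: dict[str, str] = {}
    lineno_of: dict[str, int] = {}
    seen_record = False
    entries: list[VocabularyEntry] = []
    ids_seen: set[str] = set()

    def flush() -> None:
        if not fields:
            return
        if "ID" not in fields:
            raise ValueError(
                f"vocabulary record ending near line {lineno} has no ID line"
            )
        entry = _entry_from_fields(fields, lineno_of)
        if entry.id in ids_seen:
            raise ValueError(f"duplicate vocabulary ID {entry.id!r}")
        ids_seen.add(entry.id)
        entries.append(entry)
        fields.clear()
        lineno_of.clear()

    lineno = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        code = line[:2]
        if code.isalpha() and code.isupper() and line[2:5] in ("", "   "):
            seen_record = True
        if not seen_record:
            continue  # header preamble (indented legend lines included)
        if line.startswith("//"):
            flush()
            continue
        if len(code) != 2 or not code.isalpha() or not code.isupper():
            continue
        value = line[5:].strip() if len(line) > 5 else ""
        if code in fields:
            fields[code] = f"{fields[code]} {value}"
        else:
            fields[code] = value
            lineno_of[code] = lineno
    if fields:
        flush()  # tolerate a final record without the closing //
    return Vocabulary.from_entries(entries)


def _strip_period(value: str) -> str:
    return value[:-1] if value.endswith(".") else value


def _entry_from_fields(fields: dict[str, str], lineno_of: dict[str, int]) -> VocabularyEntry:
    def mass(code: str) -> float | None:
        if code not in fields:
            return None
        try:
            return float(fields[code])
        except ValueError:
            raise ValueError(
                f"line {lineno_of[code]}: {code} value {fields[code]!r} "
                "is not a decimal number"
            ) from None

    feature_key = fields.get("FT", "other").strip()
    if feature_key not in _FEATURE_KEYS:
        feature_key = feature_key or "other"
    return VocabularyEntry(
        id=_strip_period(fields["ID"]),
        accession=fields.get("AC", ""),
        feature_key=feature_key,
        target=_strip_period(fields.get("TG", "Undefined")) or "Undefined",
        position=_strip_period(fields.get("PP", "")),
        mono_mass_delta=mass("MM"),
        avg_mass_delta=mass("MA"),
        correction_formula=fields.get("CF", ""),
        keyword=_strip_period(fields.get("KW", "")),
    )


def keyword_to_modifications(
    vocab: Vocabulary, keywords: list[str]
) -> tuple[list[VocabularyEntry], list[str]]:
    """Map PTM keywords to their exact modifications.

    Returns the concatenation, in input keyword order, of by-keyword lookups
    (deduplicated by modification id) plus the list of keywords with no
    vocabulary entry.  Unmatched keywords are a reported condition, not an
    error.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    out: list[VocabularyEntry] = []
    seen: set[str] = set()
    unmatched: list[str] = []
    for kw in keywords:
        hits = vocab.by_keyword.get(kw, [])
        if not hits:
            unmatched.append(kw)
            continue
        for entry in hits:
            if entry.id not in seen:
                seen.add(entry.id)
                out.append(entry)
    return out, unmatched


def serialize_vocabulary(vocab: Vocabulary) -> str:
    """Render a vocabulary back to ptmlist dialect (lossless for parsed fields)."""
    chunks: list[str] = []
    for e in vocab.entries:
        lines = [f"ID   {e.id}."]
        if e.accession:
            lines.append(f"AC   {e.accession}")
        if e.feature_key != "other":
            lines.append(f"FT   {e.feature_key}")
        if e.target != "Undefined":
            lines.append(f"TG   {e.target}.")
        if e.position:
            lines.append(f"PP   {e.position}.")
        if e.correction_formula:
            lines.append(f"CF   {e.correction_formula}")
        if e.mono_mass_delta is not None:
            lines.append(f"MM   {e.mono_mass_delta:.6f}")
        if e.avg_mass_delta is not None:
            lines.append(f"MA   {e.avg_mass_delta:.2f}")
        if e.keyword:
            lines.append(f"KW   {e.keyword}.")
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


def write_vocabulary_tsv(vocab: Vocabulary, path: str | Path) -> None:
    cols = [
        "id", "accession", "feature_key", "target", "position",
        "mono_mass_delta", "avg_mass_delta", "keyword",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in vocab.entries:
            row = [
                e.id, e.accession, e.feature_key, e.target, e.position,
                "" if e.mono_mass_delta is None else f"{e.mono_mass_delta:.6f}",
                "" if e.avg_mass_delta is None else f"{e.avg_mass_delta:.2f}",
                e.keyword,
            ]
            fh.write("\t".join(row) + "\n")


def read_keyword_list(source: str | Path | TextIO) -> list[str]:
    """Read a supplementary PTM keyword list: one keyword per line, '#' comments."""
    stream = _open_text(source)
    out: list[str] = []
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
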