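"""InterPro-Metal (IPM) keyword classification of protein domains.

InterPro entry descriptions (name + abstract) are searched with per-metal
case-insensitive regular-expression patterns (metal names, cofactor terms,
canonical metalloenzyme families).  Entries matching a metal's patterns
become metal-associated domains; joining them to a genome's protein ->
InterPro match table yields bioinformatic metalloprotein predictions.

Keyword hits can be spurious (an abstract may discuss a sister subfamily
that uses a different metal), so an optional manual curation table assigns
per-(entry, metal) integer scores: score 0 marks a spurious hit and excludes
it, any positive score keeps it.  The shipped default pattern file is a
plain-text data file and is meant to be replaced or extended by users.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from xml.etree import ElementTree

import pandas as pd

__all__ = [
    "InterproEntry",
    "MetalPattern",
    "load_entries",
    "load_patterns",
    "default_patterns",
    "classify_entries",
    "predict_metal_proteins",
]


@dataclass(frozen=True)
class InterproEntry:
    entry_id: str
    name: str
    abstract_text: str


@dataclass(frozen=True)
class MetalPattern:
    metal: str
    pattern: str
    note: str = ""

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


def _normalize(text: str) -> str:
    return " ".join(text.split())


def _entries_from_xml(source: str | Path) -> list[InterproEntry]:
    try:
        tree = ElementTree.parse(source)
    except ElementTree.ParseError as exc:
        raise ValueError(f"{source}: malformed InterPro XML: {exc}") from exc
    entries = []
    for node in tree.getroot().iter("interpro"):
        entry_id = node.get("id", "")
        name_node = node.find("name")
        abstract_node = node.find("abstract")
        name = _normalize("".join(name_node.itertext())) if name_node is not None else ""
        abstract = _normalize("".join(abstract_node.itertext())) if abstract_node is not None else ""
        entries.append(InterproEntry(entry_id, name, abstract))
    return entries


def _entries_from_tsv(source: str | Path) -> list[InterproEntry]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("entry_id", "name", "abstract") if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s): {', '.join(missing)}")
    return [
        InterproEntry(r.entry_id, _normalize(r.name), _normalize(r.abstract))
        for r in df.itertuples()
    ]


def load_entries(source: str | Path, format: str = "tsv") -> list[InterproEntry]:
    """Load InterPro entries from ``interpro.xml`` or a simplified TSV.

    Only entry ID, name and abstract are extracted; whitespace in abstracts
    is normalized so both formats yield identical entries for the same data.
    Duplicate entry IDs are an error.
    """
    if format == "interpro_xml":
        entries = _entries_from_xml(source)
    elif format == "tsv":
        entries = _entries_from_tsv(source)
    else:
        raise ValueError(f"unknown entry format {format!r} (use 'interpro_xml' or 'tsv')")
    seen: set[str] = set()
    for e in entries:
        if e.entry_id in seen:
            raise ValueError(f"duplicate entry_id {e.entry_id!r}")
        seen.add(e.entry_id)
    return entries


def load_patterns(source: str | Path) -> list[MetalPattern]:
    """Load metal patterns from a TSV (``metal``, ``pattern``, ``note``)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("metal", "pattern") if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s): {', '.join(missing)}")
    patterns = []
    for r in df.itertuples():
        try:
            re.compile(r.pattern)
        except re.error as exc:
            raise ValueError(f"pattern {r.pattern!r} for {r.metal} does not compile: {exc}") from exc
        patterns.append(MetalPattern(r.metal, r.pattern, getattr(r, "note", "")))
    return patterns


def default_patterns() -> list[MetalPattern]:
    """The shipped pattern set for the ten metals of the motivating study."""
    return load_patterns(files("metallomap.data") / "metal_patterns.tsv")


def classify_entries(
    entries: list[InterproEntry], patterns: list[MetalPattern]
) -> dict[str, set[str]]:
    """Map each entry to the set of metals whose patterns match its text.

    A metal is attached when any of its patterns matches the entry name or
    abstract, case-insensitively.  Order-independent and idempotent.
    """
    compiled = [(p.metal, p.compiled()) for p in patterns]
    out: dict[str, set[str]] = {}
    for e in entries:
        text = f"{e.name} {e.abstract_text}"
        out[e.entry_id] = {metal for metal, rx in compiled if rx.search(text)}
    return out


def predict_metal_proteins(
    entry_metals: dict[str, set[str]],
    curation: pd.DataFrame | None,
    matches: pd.DataFrame,
) -> pd.DataFrame:
    """Join protein->entry matches with metal-classified entries.

    ``matches`` has columns ``protein_id, entry_id``; ``curation`` (optional)
    has ``entry_id, metal, score``.  A (protein, metal) pair is predicted iff
    some matched entry carries the metal by pattern and is not curated away
    (no curation row, or score > 0).  Returns a table ``protein_id, metal,
    supporting_entries`` (comma-joined sorted entry IDs).
    """
    missing = [c for c in ("protein_id", "entry_id") if c not in matches.columns]
    if missing:
        raise ValueError(f"matches table missing column(s): {', '.join(missing)}")
    unknown = sorted(set(matches["entry_id"]) - set(entry_metals))
    if unknown:
        raise ValueError(f"matches reference unknown entries: {unknown}")
    excluded: set[tuple[str, str]] = set()
    if curation is not None and len(curation):
        cur = curation.copy()
        cur["score"] = cur["score"].astype(int)
        if (cur["score"] < 0).any():
            raise ValueError("curation scores must be >= 0")
        excluded = {
            (r.entry_id, r.metal) for r in cur.itertuples() if r.score == 0
        }
    support: dict[tuple[str, str], set[str]] = {}
    for row in matches.itertuples():
        for metal in entry_metals.get(row.entry_id, ()):
            if (row.entry_id, metal) in excluded:
                continue
            support.setdefault((row.protein_id, metal), set()).add(row.entry_id)
    rows = [
        {
            "protein_id": protein,
            "metal": metal,
            "supporting_entries": ",".join(sorted(entries)),
        }
        for (protein, metal), entries in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["protein_id", "metal", "supporting_entries"])
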