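"""Tabular data model for chromatographic fractionation experiments.

A fractionation experiment is described by three tab-separated tables:

``fractions.tsv``
    One row per chromatographic fraction: ``fraction_id``, ``separation_id``
    (the chromatographic run it belongs to), ``order_index`` (0-based elution
    order within the run), ``parent_fraction_id`` (the source fraction in a
    multi-level purification hierarchy, ``.`` when absent) and ``level``
    (column level, e.g. 2 for a second-level separation).

``metals.tsv``
    Replicate ICP-MS metal concentrations per fraction: ``fraction_id``,
    ``metal`` (element symbol), ``replicate`` (1-based) and ``concentration``
    (instrument units, non-negative).

``observations.tsv``
    MS/MS protein identifications per fraction: ``fraction_id``,
    ``protein_id`` (ORF identifier) and ``peptide_count`` (number of distinct
    peptides supporting the identification in that fraction).

Fractions are identified by opaque strings; elution order comes from
``order_index`` only, never from lexicographic ID order.  Missing optional
fields are written as ``"."``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DEFAULT_METALS",
    "Experiment",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "load_experiment",
    "write_experiment",
    "read_table",
    "write_table",
    "filter_proteins",
    "build_presence_matrix",
    "sorted_fraction_ids",
]

#: Metals measured in the motivating Pyrococcus furiosus experiment.  The
#: data model accepts any additional element symbols via ``extra_metals``.
DEFAULT_METALS = ("Co", "Fe", "Mn", "Mo", "Ni", "Pb", "U", "V", "W", "Zn")

MISSING = "."

FRACTION_COLUMNS = ["fraction_id", "separation_id", "order_index", "parent_fraction_id", "level"]
METAL_COLUMNS = ["fraction_id", "metal", "replicate", "concentration"]
OBSERVATION_COLUMNS = ["fraction_id", "protein_id", "peptide_count"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """A row references an entity that does not exist."""


class ValidationError(ValueError):
    """A value violates a data-model invariant."""


@dataclass
class Experiment:
    """In-memory bundle of the three experiment tables (validated)."""

    fractions: pd.DataFrame
    metals: pd.DataFrame
    observations: pd.DataFrame

    def copy(self) -> "Experiment":
        return Experiment(self.fractions.copy(), self.metals.copy(), self.observations.copy())


def read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    """Read a TSV table and check its header contains ``columns``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df[columns]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _to_int(df: pd.DataFrame, column: str, source: str) -> pd.Series:
    try:
        return df[column].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{source}: column {column!r} must be integer: {exc}") from exc


def _to_float(df: pd.DataFrame, column: str, source: str) -> pd.Series:
    try:
        return df[column].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{source}: column {column!r} must be numeric: {exc}") from exc


def validate_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Validate the fraction table invariants; return a typed copy."""
    df = fractions.copy()
    df["order_index"] = _to_int(df, "order_index", "fractions")
    df["level"] = _to_int(df, "level", "fractions")
    dup = df["fraction_id"][df["fraction_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate fraction_id(s): {sorted(set(dup))}")
    if (df["order_index"] < 0).any():
        raise ValidationError("order_index must be >= 0")
    if (df["level"] < 1).any():
        raise ValidationError("level must be >= 1")
    dup_order = df.duplicated(subset=["separation_id", "order_index"])
    if dup_order.any():
        bad = df.loc[dup_order, ["separation_id", "order_index"]].values.tolist()
        raise ValidationError(f"duplicate order_index within separation: {bad}")
    # parent links must reference known fractions and form a forest
    known = set(df["fraction_id"])
    parents = dict(zip(df["fraction_id"], df["parent_fraction_id"]))
    dangling = sorted(p for p in parents.values() if p != MISSING and p not in known)
    if dangling:
        raise IntegrityError(f"parent_fraction_id(s) not in table: {dangling}")
    for start in parents:
        seen = set()
        node = start
        while node != MISSING:
            if node in seen:
                raise ValidationError(f"parent links contain a cycle through {node!r}")
            seen.add(node)
            node = parents[node]
    return df


def validate_metals(
    metals: pd.DataFrame,
    fractions: pd.DataFrame,
    extra_metals: tuple[str, ...] = (),
) -> pd.DataFrame:
    df = metals.copy()
    df["replicate"] = _to_int(df, "replicate", "metals")
    df["concentration"] = _to_float(df, "concentration", "metals")
    allowed = set(DEFAULT_METALS) | set(extra_metals)
    unknown = sorted(set(df["metal"]) - allowed)
    if unknown:
        raise ValidationError(f"unknown metal symbol(s): {unknown}; extend extra_metals to accept them")
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate must be >= 1")
    if (df["concentration"] < 0).any():
        bad = df.loc[df["concentration"] < 0, "fraction_id"].tolist()
        raise ValidationError(f"negative concentration in fraction(s): {sorted(set(bad))}")
    dangling = sorted(set(df["fraction_id"]) - set(fractions["fraction_id"]))
    if dangling:
        raise IntegrityError(f"metals reference unknown fraction(s): {dangling}")
    if df.duplicated(subset=["fraction_id", "metal", "replicate"]).any():
        raise ValidationError("duplicate (fraction_id, metal, replicate) rows in metals table")
    return df


def validate_observations(observations: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Validate and aggregate protein observations.

    Duplicate (fraction, protein) rows are peptide-level records and are
    summed into a single row, after which the pair is unique.
    """
    df = observations.copy()
    if len(df):
        df["peptide_count"] = _to_int(df, "peptide_count", "observations")
        if (df["peptide_count"] < 1).any():
            raise ValidationError("peptide_count must be >= 1")
        dangling = sorted(set(df["fraction_id"]) - set(fractions["fraction_id"]))
        if dangling:
            raise IntegrityError(f"observations reference unknown fraction(s): {dangling}")
        df = (
            df.groupby(["fraction_id", "protein_id"], as_index=False, sort=False)["peptide_count"]
            .sum()
        )
    else:
        df["peptide_count"] = pd.Series([], dtype=int)
    return df[OBSERVATION_COLUMNS]


def load_experiment(
    fractions_file: str | Path,
    metals_file: str | Path,
    observations_file: str | Path,
    extra_metals: tuple[str, ...] = (),
) -> Experiment:
    """Load and validate the three experiment tables from TSV files."""
    fractions = validate_fractions(read_table(fractions_file, FRACTION_COLUMNS))
    metals = validate_metals(read_table(metals_file, METAL_COLUMNS), fractions, extra_metals)
    observations = validate_observations(read_table(observations_file, OBSERVATION_COLUMNS), fractions)
    return Experiment(fractions, metals, observations)


def canonicalize(experiment: Experiment) -> Experiment:
    """Return a copy with rows in canonical sort order (stable file output)."""
    fr = experiment.fractions.sort_values(["separation_id", "order_index"], kind="mergesort")
    me = experiment.metals.sort_values(["metal", "fraction_id", "replicate"], kind="mergesort")
    ob = experiment.observations.sort_values(["fraction_id", "protein_id"], kind="mergesort")
    return Experiment(fr.reset_index(drop=True), me.reset_index(drop=True), ob.reset_index(drop=True))


def write_experiment(experiment: Experiment, outdir: str | Path, float_format: str = "%.8g") -> dict[str, Path]:
    """Write the canonicalized experiment bundle; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = canonicalize(experiment)
    paths = {
        "fractions": outdir / "fractions.tsv",
        "metals": outdir / "metals.tsv",
        "observations": outdir / "observations.tsv",
    }
    exp.fractions.to_csv(paths["fractions"], sep="\t", index=False, lineterminator="\n")
    exp.metals.to_csv(paths["metals"], sep="\t", index=False, lineterminator="\n", float_format=float_format)
    exp.observations.to_csv(paths["observations"], sep="\t", index=False, lineterminator="\n")
    return paths


def filter_proteins(observations: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Apply the dataset-inclusion filter for confidently identified proteins.

    A protein is retained when its maximum per-fraction peptide count anywhere
    in the data set is at least ``min_peptides`` (default 2, the conventional
    two-peptide identification rule).  All rows of a retained protein are kept
    unchanged, including fractions where only one peptide was seen: a protein
    confidently identified once is trusted in all its fractions.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if not len(observations):
        return observations.copy()
    max_pep = observations.groupby("protein_id")["peptide_count"].max()
    keep = set(max_pep.index[max_pep >= min_peptides])
    return observations[observations["protein_id"].isin(keep)].reset_index(drop=True)


def sorted_fraction_ids(fractions: pd.DataFrame) -> list[str]:
    """Fraction IDs in canonical (separation_id, order_index) order."""
    return list(
        fractions.sort_values(["separation_id", "order_index"], kind="mergesort")["fraction_id"]
    )


def build_presence_matrix(observations: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Reduce peptide counts to a Boolean protein x fraction presence matrix.

    Rows are proteins in lexicographic order; columns are all fractions in
    (separation_id, order_index) order.  A cell is True iff at least one
    observation (any peptide count >= 1) exists for the pair.
    """
    cols = sorted_fraction_ids(fractions)
    dangling = sorted(set(observations["fraction_id"]) - set(cols))
    if dangling:
        raise IntegrityError(f"observations reference unknown fraction(s): {dangling}")
    proteins = sorted(set(observations["protein_id"]))
    matrix = pd.DataFrame(False, index=proteins, columns=cols, dtype=bool)
    if len(observations):
        matrix.values[
            pd.Index(proteins).get_indexer(observations["protein_id"]),
            pd.Index(cols).get_indexer(observations["fraction_id"]),
        ] = True
    matrix.index.name = "protein_id"
    matrix.columns.name = "fraction_id"
    return matrix
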