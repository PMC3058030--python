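"""Metal-peak fraction regions.

A metal peak is a contiguous run of at least two fractions, within a single
chromatographic separation, whose concentrations for a given metal stand
substantially above the surrounding baseline in every ICP-MS technical
replicate.  Manually curated peak tables are the primary path (peak calling
in the motivating study was done by inspection); :func:`detect_peaks`
formalizes the manual rule as an optional automatic detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_METALS, IntegrityError, ValidationError

__all__ = [
    "PeakRegion",
    "PeakSet",
    "load_peak_regions",
    "write_peak_regions",
    "peaksets_to_frame",
    "detect_peaks",
    "peak_fraction_count",
]


@dataclass(frozen=True)
class PeakRegion:
    """A contiguous run of fractions flagged as one metal peak."""

    peak_id: str
    metal: str
    separation_id: str
    fraction_ids: tuple[str, ...]  # in elution order

    def __post_init__(self) -> None:
        if len(self.fraction_ids) < 2:
            raise ValidationError(
                f"peak {self.peak_id!r}: a peak needs at least 2 fractions, got {len(self.fraction_ids)}"
            )


@dataclass
class PeakSet:
    """All peak regions of one metal across the experiment."""

    metal: str
    regions: list[PeakRegion] = field(default_factory=list)

    @property
    def peak_fraction_ids(self) -> frozenset[str]:
        return frozenset(f for r in self.regions for f in r.fraction_ids)

    @property
    def peak_ids(self) -> list[str]:
        return [r.peak_id for r in self.regions]


def _order_lookup(fractions: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        row.fraction_id: (row.separation_id, int(row.order_index))
        for row in fractions.itertuples()
    }


def _validate_region(
    peak_id: str,
    metal: str,
    separation_id: str,
    fraction_ids: list[str],
    lookup: dict[str, tuple[str, int]],
) -> PeakRegion:
    unknown = sorted(f for f in fraction_ids if f not in lookup)
    if unknown:
        raise IntegrityError(f"peak {peak_id!r} references unknown fraction(s): {unknown}")
    wrong_sep = sorted(f for f in fraction_ids if lookup[f][0] != separation_id)
    if wrong_sep:
        raise ValidationError(
            f"peak {peak_id!r}: fraction(s) {wrong_sep} are not in separation {separation_id!r}"
        )
    ordered = sorted(fraction_ids, key=lambda f: lookup[f][1])
    indices = [lookup[f][1] for f in ordered]
    gaps = [
        (a, b) for a, b in zip(indices, indices[1:]) if b != a + 1
    ]
    if gaps:
        raise ValidationError(
            f"peak {peak_id!r} is not contiguous: gap(s) between order_index pairs {gaps}"
        )
    return PeakRegion(peak_id, metal, separation_id, tuple(ordered))


def _check_disjoint(regions: list[PeakRegion]) -> None:
    by_sep: dict[tuple[str, str], set[str]] = {}
    for r in regions:
        key = (r.metal, r.separation_id)
        seen = by_sep.setdefault(key, set())
        overlap = seen & set(r.fraction_ids)
        if overlap:
            raise ValidationError(
                f"{r.metal} peaks overlap in separation {r.separation_id!r} "
                f"on fraction(s) {sorted(overlap)}"
            )
        seen |= set(r.fraction_ids)


def load_peak_regions(peaks_file: str | Path, fractions: pd.DataFrame) -> dict[str, PeakSet]:
    """Load manually curated peak regions from ``peaks.tsv``.

    The file has one row per member fraction (``peak_id``, ``metal``,
    ``separation_id``, ``fraction_id``); each peak must be a contiguous run
    of >= 2 fractions within one separation, and same-metal peaks within a
    separation must be disjoint.
    """
    df = pd.read_csv(peaks_file, sep="\t", dtype=str, keep_default_na=False)
    required = ["peak_id", "metal", "separation_id", "fraction_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{peaks_file}: missing required column(s): {', '.join(missing)}")
    lookup = _order_lookup(fractions)
    regions: list[PeakRegion] = []
    for (peak_id, metal, sep_id), grp in df.groupby(
        ["peak_id", "metal", "separation_id"], sort=True
    ):
        regions.append(_validate_region(peak_id, metal, sep_id, list(grp["fraction_id"]), lookup))
    _check_disjoint(regions)
    out: dict[str, PeakSet] = {}
    for r in regions:
        out.setdefault(r.metal, PeakSet(r.metal)).regions.append(r)
    return out


def peaksets_to_frame(peaksets: dict[str, PeakSet]) -> pd.DataFrame:
    rows = [
        {"peak_id": r.peak_id, "metal": r.metal, "separation_id": r.separation_id, "fraction_id": f}
        for metal in sorted(peaksets)
        for r in peaksets[metal].regions
        for f in r.fraction_ids
    ]
    return pd.DataFrame(rows, columns=["peak_id", "metal", "separation_id", "fraction_id"])


def write_peak_regions(peaksets: dict[str, PeakSet], path: str | Path) -> None:
    peaksets_to_frame(peaksets).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _local_background(values: np.ndarray, index: int, exclude: set[int], window: int) -> float:
    """Median concentration of up to ``window`` non-excluded fractions on each side."""
    n = len(values)
    picked: list[float] = []
    # walk outwards from `index` on each side until `window` background
    # fractions are collected or the separation ends
    for step in (-1, 1):
        count = 0
        j = index + step
        while 0 <= j < n and count < window:
            if j not in exclude:
                picked.append(values[j])
                count += 1
            j += step
    if not picked:
        return np.inf
    return float(np.median(picked))


def detect_peaks(
    metals: pd.DataFrame,
    fractions: pd.DataFrame,
    metal: str,
    fold: float = 3.0,
    window: int = 5,
    min_len: int = 2,
) -> PeakSet:
    """Auto-detect metal peaks by a fold-over-local-median rule.

    For each separation, a fraction is provisionally elevated when *every*
    replicate's concentration exceeds ``fold`` times that replicate's local
    background — the median over the nearest ``window`` fractions on each
    side, excluding the candidate itself.  Maximal elevated runs of length
    >= ``min_len`` are then re-confirmed against a background that excludes
    the whole candidate run, and the surviving contiguous runs become
    :class:`PeakRegion` objects.

    Requiring all replicates (rather than the mean) to clear the threshold
    is deliberately conservative and robust to single-replicate noise.
    """
    if metal not in set(metals["metal"]):
        raise ValidationError(f"unknown metal symbol {metal!r}: no measurements present")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    sub = metals[metals["metal"] == metal]
    reps = sorted(set(sub["replicate"]))
    pivot = sub.pivot_table(
        index="replicate", columns="fraction_id", values="concentration", aggfunc="first"
    )
    regions: list[PeakRegion] = []
    order = fractions.sort_values(["separation_id", "order_index"], kind="mergesort")
    for sep_id, sep_frac in order.groupby("separation_id", sort=True):
        frac_ids = list(sep_frac["fraction_id"])
        missing = [f for f in frac_ids if f not in pivot.columns]
        if missing or len(frac_ids) < min_len:
            continue
        mat = pivot.loc[reps, frac_ids].to_numpy(dtype=float)  # replicates x fractions
        n = mat.shape[1]
        # pass 1: provisional per-fraction elevation, excluding only self
        elevated = np.zeros(n, dtype=bool)
        for i in range(n):
            ok = True
            for r in range(mat.shape[0]):
                bg = _local_background(mat[r], i, {i}, window)
                if not mat[r, i] > fold * bg:
                    ok = False
                    break
            elevated[i] = ok
        # pass 2: re-confirm each run of >= min_len against run-excluded background
        confirmed = np.zeros(n, dtype=bool)
        for start, stop in _runs(elevated):
            if stop - start < min_len:
                continue
            run = set(range(start, stop))
            for i in range(start, stop):
                ok = True
                for r in range(mat.shape[0]):
                    bg = _local_background(mat[r], i, run, window)
                    if not mat[r, i] > fold * bg:
                        ok = False
                        break
                confirmed[i] = ok
        for start, stop in _runs(confirmed):
            if stop - start < min_len:
                continue
            member_ids = tuple(frac_ids[start:stop])
            peak_id = f"{metal}_{sep_id}_{sep_frac['order_index'].iloc[start]}"
            regions.append(PeakRegion(peak_id, metal, sep_id, member_ids))
    return PeakSet(metal, regions)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal True runs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def peak_fraction_count(peaks: PeakSet, universe: set[str]) -> int:
    """Number of the metal's peak fractions inside the analysis universe (f_m)."""
    return len(peaks.peak_fraction_ids & set(universe))
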