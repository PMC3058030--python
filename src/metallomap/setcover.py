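"""Greedy set cover over metal peaks.

Every metal peak must contain at least one metalloprotein, so the minimum
number of proteins needed to "touch" (share a fraction with) every peak of a
metal is a lower bound on the metal's metalloprotein count.  Minimum set
cover is NP-hard; the classical greedy algorithm — repeatedly pick the
protein covering the most still-uncovered peaks — achieves the
``(1 + ln u)`` approximation guarantee and is used here as a sanity check
against the clustering-based estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .peaks import PeakSet

__all__ = ["CoverResult", "greedy_cover"]


@dataclass
class CoverResult:
    metal: str
    chosen_proteins: list[str]
    covered: dict[str, str]  # peak_id -> protein chosen when it was first covered
    uncovered_peaks: set[str] = field(default_factory=set)

    @property
    def cover_size(self) -> int:
        return len(self.chosen_proteins)


def greedy_cover(
    matrix: pd.DataFrame,
    peaks: PeakSet,
    candidates: set[str] | None = None,
    scores: dict[str, float] | None = None,
) -> CoverResult:
    """Greedy approximate minimum protein cover of a metal's peaks.

    A protein covers a peak iff it is present in at least one of the peak's
    fractions (the peak region, not the fraction, is the unit of coverage).
    Ties on newly covered peaks are broken by lower GMPA score when
    ``scores`` is given, then by lexicographic protein ID, so the result is
    reproducible.  Peaks no candidate touches are reported in
    ``uncovered_peaks``.
    """
    if candidates is None:
        candidates = set(matrix.index)
    unknown = candidates - set(matrix.index)
    if unknown:
        raise ValueError(f"candidate protein(s) not in matrix: {sorted(unknown)}")
    covers: dict[str, set[str]] = {}
    for protein in sorted(candidates):
        present = set(matrix.columns[matrix.loc[protein]])
        touched = {r.peak_id for r in peaks.regions if present & set(r.fraction_ids)}
        if touched:
            covers[protein] = touched
    all_peaks = {r.peak_id for r in peaks.regions}
    coverable = set().union(*covers.values()) if covers else set()
    uncovered = set(coverable)
    chosen: list[str] = []
    covered: dict[str, str] = {}
    while uncovered:
        def rank(p: str) -> tuple[int, float, str]:
            return (-len(covers[p] & uncovered), (scores or {}).get(p, 0.0), p)

        best = min((p for p in covers if p not in chosen), key=rank)
        newly = covers[best] & uncovered
        if not newly:
            break
        chosen.append(best)
        for peak in sorted(newly):
            covered[peak] = best
        uncovered -= newly
    return CoverResult(
        metal=peaks.metal,
        chosen_proteins=chosen,
        covered=covered,
        uncovered_peaks=all_peaks - coverable,
    )
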