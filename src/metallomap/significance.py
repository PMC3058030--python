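"""Significance curves in GMPA score / occurrence space.

A protein's GMPA score depends strongly on how often it was observed, so a
flat score cutoff is not meaningful.  Instead, per metal, an exponential
regression curve ``score = exp(a + b * occurrences)`` is fit through all
proteins (in log space), and a *significance curve* is derived from it by
scaling the exponent: ``curve(occ) = exp(a + c * b * occ)``.

For metals with known metalloproteins (reference proteins), ``c`` is chosen
as the largest value that still captures every qualifying reference — the
minimum over references of ``(ln score_r - a) / (b * occ_r)``.  For metals
without references, ``c`` is extrapolated as the mean of the reference
metals' ratios.  Proteins at or below their metal's curve, with at least
``min_occurrences`` fraction occurrences (default 10 — little can be said
about rarely seen proteins), are deemed significantly metal-associated and
passed on to clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SignificanceCurve",
    "fit_regression",
    "set_reference_curve",
    "extrapolate_curve",
    "manual_curve",
    "filter_significant",
]

#: Slack applied on the log scale when testing "on or below the curve", so a
#: point exactly on the curve (and every qualifying reference) is included
#: despite floating-point round-off.
BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class SignificanceCurve:
    """Exponential threshold curve ``exp(a + c * b * occ)`` for one metal."""

    metal: str
    intercept_a: float
    exponent_b: float
    ratio_c: float
    source: str  # "reference" | "extrapolated" | "manual"

    def curve_ln(self, occurrences: float | np.ndarray) -> float | np.ndarray:
        return self.intercept_a + self.ratio_c * self.exponent_b * np.asarray(occurrences, dtype=float)

    def curve(self, occurrences: float | np.ndarray) -> float | np.ndarray:
        return np.exp(self.curve_ln(occurrences))


def fit_regression(results: pd.DataFrame) -> tuple[float, float]:
    """Least-squares fit of ``ln(score) = a + b * f_p`` for one metal.

    ``results`` is the per-metal slice of the GMPA score table (columns
    ``f_p`` and ``ln_score``; the floored ``ln_score`` keeps underflowed
    scores usable).  Returns ``(a, b)``.
    """
    occ = results["f_p"].to_numpy(dtype=float)
    ln = results["ln_score"].to_numpy(dtype=float)
    mask = occ >= 1
    if mask.sum() < 3:
        raise ValueError(f"regression needs >= 3 proteins with f_p >= 1, got {int(mask.sum())}")
    b, a = np.polyfit(occ[mask], ln[mask], 1)
    return float(a), float(b)


def _reference_rows(
    results: pd.DataFrame, references: set[str], min_occurrences: int
) -> pd.DataFrame:
    rows = results[results["protein_id"].isin(references)]
    return rows[rows["f_p"] >= min_occurrences]


def set_reference_curve(
    results: pd.DataFrame,
    regression: tuple[float, float],
    references: set[str],
    metal: str | None = None,
    min_occurrences: int = 10,
    c_max: float | None = None,
) -> SignificanceCurve:
    """Set the curve so every qualifying known metalloprotein is captured.

    A reference qualifies when it has a score row and ``f_p >=
    min_occurrences`` (the motivating study likewise dropped a hydrogenase
    subunit seen in only 16 fractions).  ``ratio_c`` is the minimum over
    qualifying references of ``(ln score_r - a) / (b * f_p_r)``, which makes
    the curve as stringent as possible while leaving every qualifying
    reference on or below it.  A reference whose score lies above the
    regression intercept cannot be captured by exponent scaling and raises.
    """
    a, b = regression
    metal = metal if metal is not None else _single_metal(results)
    refs = _reference_rows(results, references, min_occurrences)
    if not len(refs):
        raise ValueError(
            f"no qualifying reference for {metal} (need a scored reference with "
            f"f_p >= {min_occurrences}); use extrapolate_curve instead"
        )
    ratios = []
    for row in refs.itertuples():
        denom = b * row.f_p
        if denom == 0:
            if row.ln_score <= a + BOUNDARY_EPS:
                continue  # flat regression already captures it at any ratio
            raise ValueError(
                f"reference {row.protein_id!r} cannot be captured: flat regression (b=0) "
                f"and ln score {row.ln_score:.3g} above intercept {a:.3g}"
            )
        ratios.append((row.ln_score - a) / denom)
    c = min(ratios) if ratios else 1.0
    if c <= 0:
        raise ValueError(
            f"reference ratio for {metal} is nonpositive ({c:.3g}): a reference scores "
            "above the regression intercept and cannot be captured by exponent scaling"
        )
    if c_max is not None:
        c = min(c, c_max)
    return SignificanceCurve(metal, a, b, float(c), "reference")


def extrapolate_curve(
    regression: tuple[float, float],
    reference_curves: list[SignificanceCurve],
    metal: str = "",
) -> SignificanceCurve:
    """Curve for a metal with no usable references.

    The exponent ratio is the arithmetic mean of the reference metals'
    ratios; intercept and exponent come from this metal's own regression.
    """
    if not reference_curves:
        raise ValueError("extrapolation needs at least one reference curve")
    a, b = regression
    c = float(np.mean([rc.ratio_c for rc in reference_curves]))
    return SignificanceCurve(metal, a, b, c, "extrapolated")


def manual_curve(metal: str, intercept_a: float, exponent_b: float, ratio_c: float = 1.0) -> SignificanceCurve:
    """Hand-set curve, for users who choose thresholds by inspection."""
    return SignificanceCurve(metal, intercept_a, exponent_b, ratio_c, "manual")


def filter_significant(
    results: pd.DataFrame,
    curve: SignificanceCurve,
    min_occurrences: int = 10,
) -> set[str]:
    """Proteins at or below the curve with at least ``min_occurrences``.

    The boundary is inclusive: a protein exactly on the curve is significant.
    """
    occ = results["f_p"].to_numpy(dtype=float)
    ln = results["ln_score"].to_numpy(dtype=float)
    below = ln <= np.asarray(curve.curve_ln(occ)) + BOUNDARY_EPS
    keep = below & (occ >= min_occurrences)
    return set(results["protein_id"].to_numpy()[keep])


def _single_metal(results: pd.DataFrame) -> str:
    metals = set(results["metal"]) if "metal" in results.columns else set()
    if len(metals) == 1:
        return next(iter(metals))
    raise ValueError("pass metal= explicitly when results cover several metals")


def curves_to_frame(curves: list[SignificanceCurve], n_significant: dict[str, int] | None = None) -> pd.DataFrame:
    rows = [
        {
            "metal": c.metal,
            "intercept_a": c.intercept_a,
            "exponent_b": c.exponent_b,
            "ratio_c": c.ratio_c,
            "source": c.source,
            "n_significant": (n_significant or {}).get(c.metal, math.nan),
        }
        for c in curves
    ]
    return pd.DataFrame(rows, columns=["metal", "intercept_a", "exponent_b", "ratio_c", "source", "n_significant"])
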