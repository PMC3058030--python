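"""Global Metal Protein Association (GMPA) score.

The GMPA score of a protein/metal pair is the hypergeometric upper-tail
probability of the protein's observed overlap with the metal's peak
fractions.  With

* ``f``    — fractions in the analysis universe,
* ``f_m``  — fractions inside peaks of the metal,
* ``f_p``  — fractions in which the protein was observed,
* ``f_pm`` — protein fractions that are also metal-peak fractions,

the score is ``P(X >= f_pm)`` for ``X ~ Hypergeom(f, f_m, f_p)``: the chance
of seeing at least the observed overlap if the protein's ``f_p`` fractions
were placed uniformly at random across the fraction space.  Low scores mean
the protein co-occurs with the metal far more often than chance — the core
evidence for a metal-protein association.  Peptide-count magnitudes are
deliberately ignored: only presence/absence enters the statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .peaks import PeakSet

__all__ = [
    "SCORE_FLOOR",
    "LN_SCORE_FLOOR",
    "gmpa_score",
    "gmpa_log_score",
    "score_all",
]

#: Scores are floored at this value so downstream log-space curve fitting is
#: always well defined (strong associations underflow double precision).
SCORE_FLOOR = 1e-300
LN_SCORE_FLOOR = float(np.log(SCORE_FLOOR))

SCORE_COLUMNS = ["protein_id", "metal", "f", "f_m", "f_p", "f_pm", "score", "ln_score"]


def _check_counts(f: int, f_m: int, f_p: int, f_pm: int) -> None:
    if f < 0:
        raise ValueError(f"invalid counts: f >= 0 violated (f={f})")
    if not 0 <= f_m <= f:
        raise ValueError(f"invalid counts: 0 <= f_m <= f violated (f_m={f_m}, f={f})")
    if not 0 <= f_p <= f:
        raise ValueError(f"invalid counts: 0 <= f_p <= f violated (f_p={f_p}, f={f})")
    if not 0 <= f_pm <= min(f_p, f_m):
        raise ValueError(
            f"invalid counts: 0 <= f_pm <= min(f_p, f_m) violated "
            f"(f_pm={f_pm}, f_p={f_p}, f_m={f_m})"
        )
    if f_pm < f_p - (f - f_m):
        raise ValueError(
            f"invalid counts: f_pm >= f_p - (f - f_m) violated "
            f"(f_pm={f_pm}, f_p={f_p}, f={f}, f_m={f_m})"
        )


def gmpa_log_score(f: int, f_m: int, f_p: int, f_pm: int) -> float:
    """Natural log of the GMPA score, floored at ``LN_SCORE_FLOOR``.

    Computed as a log-sum-exp over hypergeometric log-pmf terms, which stays
    accurate far below the double-precision underflow limit of the plain
    survival function.
    """
    _check_counts(f, f_m, f_p, f_pm)
    if f_pm <= 0:
        return 0.0
    n = np.arange(f_pm, min(f_p, f_m) + 1)
    ln = float(logsumexp(hypergeom.logpmf(n, f, f_m, f_p)))
    return max(min(ln, 0.0), LN_SCORE_FLOOR)


def gmpa_score(f: int, f_m: int, f_p: int, f_pm: int) -> float:
    """GMPA score ``P(X >= f_pm)``, ``X ~ Hypergeom(f, f_m, f_p)``.

    Uses the numerically stable survival function; the result lies in
    ``(0, 1]`` and is floored at :data:`SCORE_FLOOR` on underflow.
    """
    _check_counts(f, f_m, f_p, f_pm)
    if f_pm <= 0:
        return 1.0
    s = float(hypergeom.sf(f_pm - 1, f, f_m, f_p))
    if s < SCORE_FLOOR:
        s = max(float(np.exp(gmpa_log_score(f, f_m, f_p, f_pm))), SCORE_FLOOR)
    return min(s, 1.0)


def score_all(matrix: pd.DataFrame, peaksets: dict[str, PeakSet]) -> pd.DataFrame:
    """Score every (protein, metal) pair over the presence-matrix universe.

    The analysis universe ``f`` is the matrix's fraction set; peak fractions
    outside it are ignored.  Returns a table with one row per pair and
    columns ``protein_id, metal, f, f_m, f_p, f_pm, score, ln_score``.
    """
    universe = list(matrix.columns)
    f = len(universe)
    presence = matrix.to_numpy(dtype=bool)
    f_p = presence.sum(axis=1)
    frames = []
    for metal in sorted(peaksets):
        peak_cols = matrix.columns.isin(peaksets[metal].peak_fraction_ids)
        f_m = int(peak_cols.sum())
        f_pm = presence[:, peak_cols].sum(axis=1)
        score = hypergeom.sf(f_pm - 1, f, f_m, f_p)
        score = np.minimum(score, 1.0)
        with np.errstate(divide="ignore"):
            ln = np.log(score)
        # recover log-scale values lost to survival-function underflow
        under = score < SCORE_FLOOR
        for i in np.flatnonzero(under):
            ln[i] = gmpa_log_score(f, f_m, int(f_p[i]), int(f_pm[i]))
        score = np.maximum(score, SCORE_FLOOR)
        ln = np.maximum(ln, LN_SCORE_FLOOR)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": matrix.index,
                    "metal": metal,
                    "f": f,
                    "f_m": f_m,
                    "f_p": f_p,
                    "f_pm": f_pm,
                    "score": score,
                    "ln_score": ln,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]
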