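"""Significance curves: regression fit, reference anchoring, filtering."""

import numpy as np
import pandas as pd
import pytest

from metallomap.significance import (
    SignificanceCurve,
    extrapolate_curve,
    filter_significant,
    fit_regression,
    manual_curve,
    set_reference_curve,
)


def _results(occ, ln, proteins=None, metal="Ni"):
    occ = np.asarray(occ, dtype=float)
    return pd.DataFrame(
        {
            "protein_id": proteins if proteins is not None else [f"P{i}" for i in range(len(occ))],
            "metal": metal,
            "f_p": occ,
            "ln_score": np.asarray(ln, dtype=float),
            "score": np.exp(np.asarray(ln, dtype=float)),
        }
    )


def test_noiseless_exponential_data_recovers_coefficients():
    occ = np.arange(1, 30)
    res = _results(occ, 0.5 - 0.2 * occ)
    a, b = fit_regression(res)
    assert a == pytest.approx(0.5, abs=1e-9)
    assert b == pytest.approx(-0.2, abs=1e-9)


def test_constant_scores_fit_flat():
    res = _results([1, 5, 9, 20], [0.0, 0.0, 0.0, 0.0])
    a, b = fit_regression(res)
    assert a == pytest.approx(0.0, abs=1e-12)
    assert b == pytest.approx(0.0, abs=1e-12)


def test_too_few_points_raises():
    with pytest.raises(ValueError, match=">= 3"):
        fit_regression(_results([3, 7], [-1.0, -2.0]))


def test_regression_agrees_with_independent_least_squares(default_scores):
    _, scores = default_scores
    ni = scores[scores["metal"] == "Ni"]
    a, b = fit_regression(ni)
    X = np.column_stack([np.ones(len(ni)), ni["f_p"]])
    beta, *_ = np.linalg.lstsq(X, ni["ln_score"], rcond=None)
    assert a == pytest.approx(beta[0], rel=1e-9)
    assert b == pytest.approx(beta[1], rel=1e-9)
    assert b < 0  # scores fall with occurrence count


def test_reference_on_regression_curve_gives_unit_ratio():
    a, b = 0.3, -0.15
    res = _results([20.0], [a + b * 20], proteins=["REF"])
    curve = set_reference_curve(res, (a, b), {"REF"}, metal="Ni")
    assert curve.ratio_c == pytest.approx(1.0)
    assert curve.source == "reference"


def test_reference_halfway_up_gives_half_ratio():
    a, b = 0.3, -0.15
    res = _results([20.0], [a + 0.5 * b * 20], proteins=["REF"])
    curve = set_reference_curve(res, (a, b), {"REF"}, metal="Ni")
    assert curve.ratio_c == pytest.approx(0.5)


def test_low_occurrence_references_are_excluded():
    # a reference seen in few fractions cannot anchor the curve
    a, b = 0.0, -0.2
    res = _results([6.0, 25.0], [a + 0.3 * b * 6, a + 0.9 * b * 25], proteins=["LOW", "HIGH"])
    curve = set_reference_curve(res, (a, b), {"LOW", "HIGH"}, metal="Ni", min_occurrences=10)
    assert curve.ratio_c == pytest.approx(0.9)  # LOW's 0.3 ratio is ignored


def test_no_qualifying_reference_points_to_extrapolation():
    res = _results([5.0], [-3.0], proteins=["REF"])
    with pytest.raises(ValueError, match="extrapolate"):
        set_reference_curve(res, (0.0, -0.2), {"REF"}, metal="Ni")


def test_every_qualifying_reference_passes_the_fitted_curve():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = 40
        occ = rng.integers(1, 80, size=n).astype(float)
        ln = -0.05 * occ + rng.normal(0, 1.0, size=n) - 1.0
        ln = np.minimum(ln, 0.0)
        res = _results(occ, ln)
        refs = set(rng.choice(res["protein_id"], size=5, replace=False))
        a, b = fit_regression(res)
        qualifying = res[(res["protein_id"].isin(refs)) & (res["f_p"] >= 10)]
        # references must sit below the intercept for exponent scaling to work
        if b >= 0 or not len(qualifying) or (qualifying["ln_score"] >= a).any():
            continue
        curve = set_reference_curve(res, (a, b), refs, metal="Ni")
        significant = filter_significant(res, curve)
        assert set(qualifying["protein_id"]) <= significant
        for row in qualifying.itertuples():
            assert row.score <= float(curve.curve(row.f_p)) * (1 + 1e-12)


@pytest.mark.parametrize("ratios, expected", [([0.4, 0.6], 0.5), ([0.7], 0.7)])
def test_extrapolated_ratio_is_mean_of_reference_ratios(ratios, expected):
    refs = [SignificanceCurve("Fe", -1.0, -0.1, r, "reference") for r in ratios]
    curve = extrapolate_curve((-0.5, -0.08), refs, metal="Pb")
    assert curve.ratio_c == pytest.approx(expected)
    assert (curve.intercept_a, curve.exponent_b) == (-0.5, -0.08)
    assert curve.source == "extrapolated"


def test_extrapolation_requires_reference_curves():
    with pytest.raises(ValueError, match="reference"):
        extrapolate_curve((-0.5, -0.08), [])


def test_occurrence_cutoff_excludes_rare_proteins():
    curve = manual_curve("Ni", 0.0, -0.1, 1.0)
    res = _results([9.0, 10.0], [-50.0, -50.0], proteins=["RARE", "OK"])
    assert filter_significant(res, curve, min_occurrences=10) == {"OK"}


def test_point_exactly_on_curve_is_included():
    curve = manual_curve("Ni", -0.2, -0.1, 1.5)
    occ = 14.0
    res = _results([occ], [float(curve.curve_ln(occ))], proteins=["EDGE"])
    assert filter_significant(res, curve, min_occurrences=10) == {"EDGE"}


def test_larger_min_occurrences_never_admits_more():
    rng = np.random.default_rng(23)
    res = _results(rng.integers(1, 60, size=50).astype(float), -rng.uniform(0, 30, size=50))
    curve = manual_curve("Ni", 0.0, -0.2, 1.0)
    previous = None
    for cut in (5, 10, 20, 40):
        current = filter_significant(res, curve, min_occurrences=cut)
        if previous is not None:
            assert current <= previous
        previous = current


def test_steeper_curve_is_subset_of_regression_set(default_scores):
    # with b < 0 and ratio_c >= 1 the significance curve lies below the
    # regression curve for occ > 0, so its significant set is a subset
    _, scores = default_scores
    ni = scores[scores["metal"] == "Ni"]
    a, b = fit_regression(ni)
    assert b < 0
    refs = set(ni.loc[ni["score"].rank(method="first") <= 5, "protein_id"])
    curve = set_reference_curve(ni, (a, b), refs, metal="Ni")
    if curve.ratio_c >= 1:
        regression_set = filter_significant(ni, manual_curve("Ni", a, b, 1.0))
        assert filter_significant(ni, curve) <= regression_set
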