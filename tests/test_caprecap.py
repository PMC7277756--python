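"""Log-linear capture-recapture: fits, selection, profile intervals."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from admin_prev import (
    CaptureTable,
    capture_recapture_report,
    enumerate_models,
    fit_all_models,
    fit_loglinear,
    lincoln_petersen,
    model_selection,
    mu000_closed_form,
    profile_ci,
    undercount_percent,
)
from admin_prev.caprecap import OBSERVED_PATTERNS

EXAMPLE = CaptureTable(n100=100, n010=60, n001=40,
                       n110=30, n101=20, n011=12, n111=6)


def test_enumerate_models_is_the_hierarchical_family():
    models = enumerate_models()
    assert len(models) == 8
    assert models[0] == ()
    assert models[-1] == ("AB", "AC", "BC")
    assert all("ABC" not in m for m in models)


def test_capture_table_validation_and_construction():
    with pytest.raises(ValueError):
        CaptureTable(-1, 0, 0, 0, 0, 0, 0)
    t = CaptureTable.from_patterns([(1, 0, 0), (1, 0, 0), (1, 1, 1)])
    assert t.n100 == 2 and t.n111 == 1 and t.n_obs == 3
    with pytest.raises(ValueError):
        CaptureTable.from_patterns([(0, 0, 0)])


def test_all_pairwise_model_matches_odds_ratio_identity():
    # mu000 = n100 n010 n001 n111 / (n110 n101 n011) = 200 for the example
    assert mu000_closed_form(EXAMPLE) == pytest.approx(200.0)
    fit = fit_loglinear(EXAMPLE, ("AB", "AC", "BC"))
    assert fit.mu000_hat == pytest.approx(200.0, abs=1e-6)
    assert fit.n_hat == pytest.approx(468.0, abs=1e-6)


def test_saturated_fit_reproduces_observed_cells():
    fit = fit_loglinear(EXAMPLE, ("AB", "AC", "BC"))
    np.testing.assert_allclose(fit.fitted_cells, EXAMPLE.counts, atol=1e-6)
    assert fit.g2 == pytest.approx(0.0, abs=1e-8)
    assert fit.df == 0


def test_two_source_reduction_matches_lincoln_petersen():
    # source C never captures: independence fit collapses to Lincoln-Petersen
    t = CaptureTable(n100=150, n010=100, n001=0, n110=50, n101=0, n011=0,
                     n111=0)
    fit = fit_loglinear(t, ())
    assert fit.dropped_sources == ("C",)
    n_a, n_b, n_ab = 150 + 50, 100 + 50, 50
    assert lincoln_petersen(n_a, n_b, n_ab) == pytest.approx(600.0)
    assert fit.n_hat == pytest.approx(600.0, abs=1e-6)


def test_independence_fit_agrees_with_statsmodels_glm():
    X = np.column_stack(
        [np.ones(7), np.asarray(OBSERVED_PATTERNS, dtype=float)]
    )
    res = sm.GLM(EXAMPLE.counts, X, family=sm.families.Poisson()).fit()
    fit = fit_loglinear(EXAMPLE, ())
    np.testing.assert_allclose(
        list(fit.coefficients.values()), res.params, atol=1e-6
    )


def test_fitted_totals_match_observed_for_every_model():
    for interactions in enumerate_models():
        fit = fit_loglinear(EXAMPLE, interactions)
        assert fit.fitted_cells.sum() == pytest.approx(EXAMPLE.n_obs,
                                                       abs=1e-8)


def test_adding_interactions_never_increases_deviance():
    g2 = {m: fit_loglinear(EXAMPLE, m).g2 for m in enumerate_models()}
    for m in enumerate_models():
        for pair in ("AB", "AC", "BC"):
            if pair not in m:
                bigger = tuple(sorted(set(m) | {pair}))
                key = tuple(p for p in ("AB", "AC", "BC") if p in bigger)
                assert g2[key] <= g2[m] + 1e-8


@settings(deadline=None, max_examples=60)
@given(
    cells=st.lists(st.integers(5, 400), min_size=7, max_size=7)
)
def test_closed_form_identity_on_random_positive_tables(cells):
    t = CaptureTable(*cells)
    fit = fit_loglinear(t, ("AB", "AC", "BC"))
    assert fit.mu000_hat == pytest.approx(mu000_closed_form(t), rel=1e-6)


def test_model_selection_criteria_and_tie_break():
    fits = fit_all_models(EXAMPLE)
    ranked, best = model_selection(fits)
    saturated = next(f for f in fits if len(f.interactions) == 3)
    # deviance-relative convention: saturated model has AIC = 0 - 0 = 0
    assert saturated.aic == pytest.approx(0.0, abs=1e-8)
    assert best.aic == min(f.aic for f in fits)
    # equal AIC resolves toward the smaller interaction set
    order = [(f.aic, len(f.interactions)) for f in ranked]
    assert order == sorted(order)


def test_bic_selection_prefers_independence_on_independent_data():
    # consistency oracle: product-form tables at n=10^4 should be assigned
    # to the independence model almost always under the log(n) penalty
    rng = np.random.default_rng(99)
    p = np.array([0.0216, 0.1386, 0.0616, 0.1134, 0.0504, 0.3234, 0.2646])
    p = p / p.sum()
    wins = 0
    n_tables = 200
    for _ in range(n_tables):
        counts = rng.multinomial(10_000, p)
        _, best = model_selection(fit_all_models(CaptureTable(*counts)),
                                  criterion="bic")
        wins += best.interactions == ()
    assert wins >= int(0.90 * n_tables)


def test_profile_ci_contains_estimate_and_collapses_at_tiny_level():
    lo, hi, open_upper = profile_ci(EXAMPLE, ("AB", "AC", "BC"), level=0.95)
    fit = fit_loglinear(EXAMPLE, ("AB", "AC", "BC"))
    assert lo <= fit.n_hat <= hi and not open_upper
    lo2, hi2, _ = profile_ci(EXAMPLE, ("AB", "AC", "BC"), level=0.001,
                             tol=0.05)
    assert hi2 - lo2 < 1.0
    assert lo2 <= fit.n_hat <= hi2


def test_undercount_percent_arithmetic():
    assert undercount_percent(5508, 5362) == pytest.approx(2.723, abs=1e-3)
    assert undercount_percent(100, 100) == 0.0
    assert undercount_percent(200, 100) == 100.0
    with pytest.raises(ValueError):
        undercount_percent(10, 0)


def test_report_structure_and_consistency():
    report = capture_recapture_report(EXAMPLE)
    assert len(report["fits"]) == 8
    assert report["n_obs"] == EXAMPLE.n_obs
    assert report["ci"][0] <= report["n_hat"] <= report["ci"][1]
    assert report["undercount_percent"] == pytest.approx(
        round(100 * (report["n_hat"] - EXAMPLE.n_obs) / EXAMPLE.n_obs, 1)
    )


def test_boundary_zero_cell_is_flagged_not_corrected():
    t = CaptureTable(n100=50, n010=40, n001=30, n110=20, n101=10, n011=5,
                     n111=0)
    fit = fit_loglinear(t, ("AB", "AC", "BC"))
    assert fit.boundary
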