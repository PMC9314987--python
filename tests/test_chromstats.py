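"""Regression fit, X-deviation arithmetic and the studentised outlier test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asmcompare.chromstats import (deviation_table, fit_autosome_regression,
                                   outlier_test, poisson_glm_deviation,
                                   simulate_count_table, x_deviation)


def _table(lengths, counts, x_length=None, x_count=None, category="DEL"):
    lengths, counts = list(lengths), list(counts)
    is_x = [False] * len(lengths)
    names = [f"chr{i+1}" for i in range(len(lengths))]
    if x_length is not None:
        lengths.append(x_length)
        counts.append(x_count)
        is_x.append(True)
        names.append("chrX")
    return pd.DataFrame({"length": lengths, "is_x": is_x, category: counts},
                        index=pd.Index(names, name="chrom"))


def test_exact_linear_counts_recover_slope_and_r2():
    lengths = np.arange(1, 7) * 1e6
    table = _table(lengths, 2e-6 * lengths)
    fit = fit_autosome_regression(table, "DEL")
    assert fit.slope == pytest.approx(2e-6, rel=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_constant_counts_give_zero_slope_zero_r2():
    table = _table(np.arange(1, 7) * 1e6, [7] * 6)
    fit = fit_autosome_regression(table, "DEL")
    assert fit.slope == 0.0 and fit.r_squared == 0.0


def test_fit_requires_three_autosomes_and_length_variance():
    with pytest.raises(ValueError, match="3 autosomes"):
        fit_autosome_regression(_table([1e6, 2e6], [1, 2]), "DEL")
    with pytest.raises(ValueError, match="variance"):
        fit_autosome_regression(_table([1e6] * 5, [1, 2, 3, 4, 5]), "DEL")


def test_x_row_excluded_from_fit():
    lengths = np.arange(1, 7) * 1e6
    with_x = _table(lengths, 2e-6 * lengths, x_length=3e6, x_count=5000)
    fit = fit_autosome_regression(with_x, "DEL")
    assert fit.slope == pytest.approx(2e-6, rel=1e-12)
    assert fit.n == 6


def test_ols_matches_statsmodels_on_random_tables(rng):
    import statsmodels.api as sm

    for _ in range(100):
        n = int(rng.integers(3, 25))
        lengths = rng.uniform(4e7, 3e8, size=n)
        counts = rng.uniform(0, 500, size=n)
        table = _table(lengths, counts)
        fit = fit_autosome_regression(table, "DEL")
        X = sm.add_constant(lengths)
        res = sm.OLS(counts, X).fit()
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-9, abs=1e-9)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-9)
        assert fit.r_squared == pytest.approx(res.rsquared, rel=1e-9, abs=1e-12)
        assert fit.residual_var == pytest.approx(res.mse_resid, rel=1e-9, abs=1e-12)


def test_poisson_slope_recovery_over_many_seeds():
    """Counts ~ Poisson(3 per Mb): mean fitted slope within 2 SE of 3e-6."""
    slopes = []
    rng = np.random.default_rng(77)
    lengths = np.linspace(6e7, 2.7e8, 18)
    for _ in range(200):
        counts = rng.poisson(3e-6 * lengths)
        fit = fit_autosome_regression(_table(lengths, counts), "DEL")
        slopes.append(fit.slope)
    se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 3e-6) <= 2 * se


# ---------------------------------------------------------------------------
# deviation arithmetic


def _fixed_fit(lengths=None, counts=None):
    lengths = np.arange(1, 19) * 1.5e7 if lengths is None else lengths
    rng = np.random.default_rng(5)
    counts = 100 + 2e-6 * lengths + rng.normal(0, 8, len(lengths)) \
        if counts is None else counts
    return fit_autosome_regression(_table(lengths, counts), "DEL")


def test_deviation_examples():
    fit = _fixed_fit()
    # fabricate the spec-level arithmetic by overriding the prediction
    fit.intercept, fit.slope = 100.0, 0.0
    dev = x_deviation(fit, x_length=1e8, x_observed=25, ne_factor=0.75)
    assert dev.x_expected_adjusted == pytest.approx(75.0)
    assert dev.deviation_pct == pytest.approx(-66.6667, abs=1e-3)
    dev = x_deviation(fit, x_length=1e8, x_observed=150, ne_factor=0.75)
    assert dev.deviation_pct == pytest.approx(100.0)
    dev = x_deviation(fit, x_length=1e8, x_observed=100, ne_factor=1.0)
    assert dev.deviation_pct == pytest.approx(0.0)
    assert dev.deviation_pct_unadjusted == pytest.approx(0.0)


def test_deviation_sign_coherence():
    fit = _fixed_fit()
    for observed in (1, 50, 200, 1000):
        dev = x_deviation(fit, 1e8, observed)
        assert (dev.deviation_pct < 0) == (observed < dev.x_expected_adjusted)


def test_non_positive_expectation_is_an_error():
    fit = _fixed_fit()
    fit.intercept, fit.slope = 0.0, 0.0
    with pytest.raises(ValueError, match="non-positive"):
        x_deviation(fit, 1e8, 10)


# ---------------------------------------------------------------------------
# outlier test


def test_observation_on_the_line_gives_t0_p1():
    fit = _fixed_fit()
    t, p = outlier_test(fit, 1e8, fit.predict(1e8))
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_zero_residual_variance_not_computable():
    lengths = np.arange(1, 19) * 1.5e7
    fit = _fixed_fit(lengths, 2e-6 * lengths)  # exact line
    t, p = outlier_test(fit, 1e8, 500)
    assert t is None and p is None


def test_outlier_five_se_below_matches_t_tail_oracle():
    fit = _fixed_fit()
    se = np.sqrt(fit.residual_var * (1 + 1 / fit.n
                                     + (1e8 - fit.mean_length) ** 2 / fit.sxx))
    observed = fit.predict(1e8) - 5 * se
    t, p = outlier_test(fit, 1e8, observed)
    assert t == pytest.approx(-5.0)
    assert p == pytest.approx(2 * stats.t.sf(5.0, fit.n - 2), rel=1e-12)
    assert p < 0.001


def test_p_value_monotone_in_residual_magnitude():
    fit = _fixed_fit()
    pred = fit.predict(1e8)
    ps = [outlier_test(fit, 1e8, pred + delta)[1] for delta in (5, 20, 80, 320)]
    assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# planted deficiency recovery and the GLM cross-check


def test_planted_deficiency_recovered(rng):
    devs, sig = [], 0
    n_seeds = 200
    for _ in range(n_seeds):
        table = simulate_count_table(rng, x_deficiency=0.5)
        dev = deviation_table(table, ["DEL"]).iloc[0]
        devs.append(dev["deviation_pct"])
        if dev["p_value"] < 0.001:
            sig += 1
    assert -55.0 <= np.mean(devs) <= -45.0
    assert sig >= 0.95 * n_seeds


def test_glm_mode_agrees_on_the_verdict(rng):
    table = simulate_count_table(rng, x_deficiency=0.5)
    ols = deviation_table(table, ["DEL"]).iloc[0]
    glm = poisson_glm_deviation(table, "DEL")
    assert glm.deviation_pct == pytest.approx(ols["deviation_pct"], abs=15.0)
    assert glm.p_value < 0.01


def test_deviation_table_flags_x_row_requirements():
    with pytest.raises(ValueError, match="exactly one X"):
        deviation_table(_table([1e6, 2e6, 3e6], [1, 2, 3]), ["DEL"])
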