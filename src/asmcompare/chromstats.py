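"""Chromosome-length regression and X-chromosome deviation statistics.

Under neutral, uniform accumulation the count of events on a chromosome is
proportional to its length, so ordinary least squares of count on length
over the autosomes gives the expectation for any chromosome.  The X is then
judged against that model twice over:

* an *outlier test*: the externally studentised prediction residual of the
  X count treated as a new observation, ``t = (obs - pred) / SE_pred`` with
  ``SE_pred = s * sqrt(1 + 1/n + (L_X - mean(L))^2 / Sxx)``, two-sided
  p-value on n - 2 degrees of freedom;
* a *deficiency/excess rate*: the signed percentage deviation of the
  observed X count from its expectation after scaling by the relative
  effective population size of the X.  With three males' X chromosomes for
  every four autosome sets, Ne(X)/Ne(autosome) is roughly 3/4, so the
  adjusted expectation is ``0.75 * prediction`` by default.  The unadjusted
  deviation is always co-reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_NE_FACTOR = 0.75
_VAR_EPS = 1e-12


@dataclass
class RegressionFit:
    """OLS of event count on chromosome length over autosomes."""

    slope: float           # events per bp
    intercept: float
    r_squared: float
    residual_var: float    # s^2 on n - 2 df
    n: int
    mean_length: float
    sxx: float

    def predict(self, length: float) -> float:
        return self.intercept + self.slope * length


@dataclass
class DeviationResult:
    """X-chromosome observed vs expected for one event category."""

    category: str
    fit: RegressionFit
    x_length: float
    x_observed: float
    x_predicted: float
    ne_factor: float
    x_expected_adjusted: float
    deviation_pct: float            # negative = deficiency, positive = excess
    deviation_pct_unadjusted: float
    t_statistic: float | None
    p_value: float | None           # None when not computable


def fit_autosome_regression(
    table: pd.DataFrame,
    category: str,
) -> RegressionFit:
    """OLS fit of ``table[category]`` on ``table['length']`` over autosomes.

    ``table`` is a per-chromosome count table with ``length`` and ``is_x``
    columns; the X row is excluded from the fit.
    """
    if category not in table.columns:
        raise ValueError(f"unknown category {category}")
    auto = table[~table["is_x"].astype(bool)]
    x = auto["length"].to_numpy(dtype=float)
    y = auto[category].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 autosomes to fit the regression")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= _VAR_EPS:
        raise ValueError("zero variance in chromosome lengths")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # constant counts carry no explainable variance: R^2 is 0 by convention
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > _VAR_EPS else 0.0
    residual_var = ss_res / (x.size - 2)
    return RegressionFit(slope, intercept, r_squared, residual_var,
                         int(x.size), float(x.mean()), sxx)


def outlier_test(fit: RegressionFit, x_length: float,
                 x_observed: float) -> tuple[float | None, float | None]:
    """Studentised prediction-residual t test of X as a new observation.

    Returns ``(t, p)``; both are None when the autosome fit has (near) zero
    residual variance, where the test is not computable.
    """
    if fit.residual_var <= _VAR_EPS:
        return None, None
    se = float(np.sqrt(fit.residual_var
                       * (1.0 + 1.0 / fit.n
                          + (x_length - fit.mean_length) ** 2 / fit.sxx)))
    t = (x_observed - fit.predict(x_length)) / se
    p = 2.0 * float(stats.t.sf(abs(t), fit.n - 2))
    return float(t), p


def x_deviation(
    fit: RegressionFit,
    x_length: float,
    x_observed: float,
    ne_factor: float = DEFAULT_NE_FACTOR,
    category: str = "",
) -> DeviationResult:
    """Ne-adjusted deficiency/excess of the X against the autosome model."""
    x_predicted = fit.predict(x_length)
    adjusted = ne_factor * x_predicted
    if adjusted <= 0:
        raise ValueError(
            f"non-positive adjusted expectation ({adjusted:.3g}) for {category!r}")
    deviation = 100.0 * (x_observed - adjusted) / adjusted
    unadjusted = 100.0 * (x_observed - x_predicted) / x_predicted
    t, p = outlier_test(fit, x_length, x_observed)
    return DeviationResult(
        category=category, fit=fit, x_length=x_length, x_observed=x_observed,
        x_predicted=x_predicted, ne_factor=ne_factor,
        x_expected_adjusted=adjusted, deviation_pct=deviation,
        deviation_pct_unadjusted=unadjusted, t_statistic=t, p_value=p,
    )


def deviation_table(
    table: pd.DataFrame,
    categories: list[str],
    ne_factor: float = DEFAULT_NE_FACTOR,
) -> pd.DataFrame:
    """X-deviation summary over several count categories of one table."""
    x_rows = table[table["is_x"].astype(bool)]
    if len(x_rows) != 1:
        raise ValueError("count table must flag exactly one X chromosome")
    x_length = float(x_rows["length"].iloc[0])
    rows = []
    for cat in categories:
        fit = fit_autosome_regression(table, cat)
        try:
            dev = x_deviation(fit, x_length, float(x_rows[cat].iloc[0]),
                              ne_factor, category=cat)
        except ValueError:
            # too few events in this category for a meaningful expectation
            rows.append({"category": cat, "slope_per_mb": fit.slope * 1e6,
                         "intercept": fit.intercept, "r_squared": fit.r_squared,
                         "x_observed": float(x_rows[cat].iloc[0]),
                         "x_predicted": fit.predict(x_length),
                         "x_expected_adjusted": np.nan, "deviation_pct": np.nan,
                         "deviation_pct_unadjusted": np.nan, "t": np.nan,
                         "p_value": np.nan})
            continue
        rows.append({
            "category": cat,
            "slope_per_mb": fit.slope * 1e6,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "x_observed": dev.x_observed,
            "x_predicted": dev.x_predicted,
            "x_expected_adjusted": dev.x_expected_adjusted,
            "deviation_pct": dev.deviation_pct,
            "deviation_pct_unadjusted": dev.deviation_pct_unadjusted,
            "t": dev.t_statistic,
            "p_value": dev.p_value,
        })
    return pd.DataFrame(rows)


def simulate_count_table(
    rng: np.random.Generator,
    n_autosomes: int = 18,
    rate_per_mb: float = 3.0,
    x_deficiency: float = 0.0,
    ne_factor: float = DEFAULT_NE_FACTOR,
    category: str = "DEL",
) -> pd.DataFrame:
    """Poisson counts on a pig-like karyotype with an optional planted X deficit.

    Autosome lengths span 60-274 Mb (18 autosomes by default, the pig
    complement); the X is 126 Mb.  Counts are Poisson with mean
    ``rate_per_mb * length``; the X mean is additionally scaled by
    ``ne_factor`` (its relative effective population size) and by
    ``1 - x_deficiency`` (the planted deficit on the adjusted scale).
    """
    lengths = np.linspace(274e6, 60e6, n_autosomes)
    x_length = 126e6
    lam = rate_per_mb * lengths / 1e6
    counts = rng.poisson(lam)
    x_lam = rate_per_mb * x_length / 1e6 * ne_factor * (1.0 - x_deficiency)
    x_count = rng.poisson(x_lam)
    table = pd.DataFrame({
        "length": np.append(lengths, x_length),
        "is_x": [False] * n_autosomes + [True],
        category: np.append(counts, x_count),
    }, index=pd.Index([f"chr{i+1}" for i in range(n_autosomes)] + ["chrX"],
                      name="chrom"))
    return table


def poisson_glm_deviation(
    table: pd.DataFrame,
    category: str,
    ne_factor: float = DEFAULT_NE_FACTOR,
) -> DeviationResult:
    """Sensitivity-analysis variant: Poisson GLM (log link, length offset).

    The linear OLS model is the primary analysis; this mode checks that the
    deficiency/excess verdict is not an artefact of assuming Gaussian noise
    on counts.
    """
    import statsmodels.api as sm

    auto = table[~table["is_x"].astype(bool)]
    x_rows = table[table["is_x"].astype(bool)]
    if len(x_rows) != 1:
        raise ValueError("count table must flag exactly one X chromosome")
    y = auto[category].to_numpy(dtype=float)
    offset = np.log(auto["length"].to_numpy(dtype=float))
    model = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Poisson(),
                   offset=offset)
    res = model.fit()
    x_length = float(x_rows["length"].iloc[0])
    x_observed = float(x_rows[category].iloc[0])
    x_predicted = float(np.exp(res.params[0]) * x_length)
    adjusted = ne_factor * x_predicted
    deviation = 100.0 * (x_observed - adjusted) / adjusted
    unadjusted = 100.0 * (x_observed - x_predicted) / x_predicted
    p = float(stats.poisson.cdf(x_observed, adjusted))
    p = 2.0 * min(p, 1.0 - stats.poisson.cdf(x_observed - 1, adjusted))
    ols = fit_autosome_regression(table, category)
    return DeviationResult(
        category=category, fit=ols, x_length=x_length, x_observed=x_observed,
        x_predicted=x_predicted, ne_factor=ne_factor,
        x_expected_adjusted=adjusted, deviation_pct=deviation,
        deviation_pct_unadjusted=unadjusted, t_statistic=None,
        p_value=min(p, 1.0),
    )
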