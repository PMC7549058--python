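"""Validation-study statistics: per-item random-slope mixed models and the
loadings-versus-coefficients correlation.

Each of the 18 adjectives is analyzed with a linear mixed model of the
stimulus ratings::

    score = b0 + bV*V + bD*D + (u0 + uV*V + uD*D)_rater + eps

where V and D are the stimulus's valence and dominance levels in SD units
(continuous), raters contribute random intercepts and random slopes, and
fitting is by REML.  Fixed-slope p-values are Wald z tests; Bonferroni
correction is applied per dimension across the 18 items.

The key summary statistic is the Pearson correlation between the
impression-PCA loadings of the 18 items on one dimension and their fitted
mixed-model slopes for a manipulated dimension: a high matched-dimension
correlation with near-zero crossed correlations shows that transforming the
face along one impression dimension moves exactly the impressions that load
on it.  Published reference versions of both 18-item tables ship with the
package (transcribed at their printed 2-decimal precision) so this statistic
can be recomputed without any raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LMEItemFit",
    "CorrelationResult",
    "fit_random_slope_lme",
    "fit_all_items",
    "bonferroni",
    "correlate_loadings_coefficients",
    "load_reference_loadings",
    "load_reference_lme_coefficients",
]


@dataclass
class LMEItemFit:
    """Fixed effects and variance components for one adjective's mixed model."""

    item: str
    intercept: float
    beta_valence: float
    beta_dominance: float
    se_valence: float
    se_dominance: float
    p_valence: float
    p_dominance: float
    p_valence_adj: float | None = None
    p_dominance_adj: float | None = None
    rater_intercept_sd: float = np.nan
    rater_valence_slope_sd: float = np.nan
    rater_dominance_slope_sd: float = np.nan
    residual_sd: float = np.nan
    boundary: bool = False  # variance component at (or near) zero / singular fit


@dataclass
class CorrelationResult:
    """Pearson correlation with t test and Fisher-z confidence interval."""

    r: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float


def fit_random_slope_lme(long_ratings: pd.DataFrame, item: str) -> LMEItemFit:
    """Fit the random-intercept, random-slope mixed model for one item.

    ``long_ratings`` needs columns rater, item, valence_level,
    dominance_level, score.  Requires at least two raters and at least two
    distinct levels per dimension.  A singular random-effects covariance is
    flagged via ``boundary`` but estimates are still returned.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = long_ratings.loc[long_ratings["item"] == item].copy()
    if df.empty:
        raise ValueError(f"no rows for item {item!r}")
    if df["rater"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 raters")
    for col in ("valence_level", "dominance_level"):
        if df[col].nunique() < 2:
            raise ValueError(f"{col} must span at least 2 distinct values")
    df = df.rename(columns={"valence_level": "V", "dominance_level": "D"})
    boundary = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm("score ~ V + D", df, groups=df["rater"], re_formula="~V + D")
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    cov_re = np.asarray(fit.cov_re)
    if not fit.converged or np.any(np.diag(cov_re) < 1e-8):
        boundary = True
    params = fit.params
    bse = fit.bse
    z_v = params["V"] / bse["V"]
    z_d = params["D"] / bse["D"]
    re_sd = np.sqrt(np.clip(np.diag(cov_re), 0.0, None))
    return LMEItemFit(
        item=item,
        intercept=float(params["Intercept"]),
        beta_valence=float(params["V"]),
        beta_dominance=float(params["D"]),
        se_valence=float(bse["V"]),
        se_dominance=float(bse["D"]),
        p_valence=float(2 * stats.norm.sf(abs(z_v))),
        p_dominance=float(2 * stats.norm.sf(abs(z_d))),
        rater_intercept_sd=float(re_sd[0]),
        rater_valence_slope_sd=float(re_sd[1]) if re_sd.size > 1 else np.nan,
        rater_dominance_slope_sd=float(re_sd[2]) if re_sd.size > 2 else np.nan,
        residual_sd=float(np.sqrt(fit.scale)),
        boundary=boundary,
    )


def fit_all_items(long_ratings: pd.DataFrame) -> pd.DataFrame:
    """Fit every item's mixed model and apply per-dimension Bonferroni correction."""
    items = list(pd.unique(long_ratings["item"]))
    fits = [fit_random_slope_lme(long_ratings, it) for it in items]
    m = len(items)
    pv_adj = bonferroni([f.p_valence for f in fits], m)
    pd_adj = bonferroni([f.p_dominance for f in fits], m)
    for f, pv, pdd in zip(fits, pv_adj, pd_adj):
        f.p_valence_adj = pv
        f.p_dominance_adj = pdd
    return pd.DataFrame(
        {
            "item": [f.item for f in fits],
            "intercept": [f.intercept for f in fits],
            "beta_valence": [f.beta_valence for f in fits],
            "beta_dominance": [f.beta_dominance for f in fits],
            "se_valence": [f.se_valence for f in fits],
            "se_dominance": [f.se_dominance for f in fits],
            "p_valence": [f.p_valence for f in fits],
            "p_dominance": [f.p_dominance for f in fits],
            "p_valence_adj": pv_adj,
            "p_dominance_adj": pd_adj,
            "boundary": [f.boundary for f in fits],
        }
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * m)`` with m comparisons (default len)."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, v * m) for v in p]


def correlate_loadings_coefficients(
    loadings: np.ndarray, coefficients: np.ndarray
) -> CorrelationResult:
    """Pearson correlation between item loadings and mixed-model slopes.

    Returns r, the t statistic with ``df = n - 2``, the two-sided p-value and
    a 95% Fisher-z confidence interval.  The result is invariant to affine
    rescaling of either input.
    """
    x = np.asarray(loadings, dtype=float)
    y = np.asarray(coefficients, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    n = x.size
    r, p = stats.pearsonr(x, y)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        lo = hi = r
    else:
        t = r * np.sqrt(df / (1 - r * r))
        zcrit = stats.norm.ppf(0.975)
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(r=float(r), t=float(t), df=df, p=float(p),
                             ci_low=float(lo), ci_high=float(hi))


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("impressionface.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_loadings() -> pd.DataFrame:
    """Published 18-item impression-PCA loading table (2-decimal precision)."""
    return _load_table("reference_loadings.csv")


def load_reference_lme_coefficients() -> pd.DataFrame:
    """Published 18-item validation-study mixed-model coefficient table."""
    return _load_table("reference_lme_coefficients.csv")
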