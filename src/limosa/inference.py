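"""Statistical battery for the wintering-distribution analysis.

Four families of tests:

* a site effect on session-level sex-ratio logits, as a Gaussian
  likelihood-ratio chi-square (site factor vs intercept-only);
* one-way ANOVA with Tukey-Kramer all-pairs contrasts for layer
  biomass differences between sites;
* Pearson correlations, including the four-way hypothesis panel that
  pits the cost (Bergmann) hypothesis against resource partitioning;
* ordinary least-squares fits for the cost-distance and
  condition-score (APS ~ cost x sex) relations.

With one observation per scan session a mixed model with a session
random effect is confounded with the residual, so the site test is the
fixed-effects Gaussian LRT on session logits (df = sites - 1).  The
chi-square statistic is reported as such, but its p-value is computed
through the exact monotone F transformation, which is properly
calibrated at small sample sizes where the chi-square reference is
anticonservative.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .fieldobs import session_logits
from .result import TestResult, P_FLOOR

__all__ = [
    "site_effect_test",
    "one_way_anova",
    "tukey_hsd",
    "pearson_test",
    "linear_fit",
    "LinearFitResult",
    "hypothesis_panel",
]


def site_effect_test(sessions: pd.DataFrame) -> TestResult:
    """Likelihood-ratio test for a site effect on session sex-ratio logits.

    Compares Gaussian models of the adjusted session logits with and
    without the site factor: chi2 = n * ln(RSS0/RSS1), df = k - 1.
    """
    sites = sessions["site"].unique()
    k = len(sites)
    if k < 2:
        raise ValueError("site_effect_test needs sessions from >= 2 sites")
    logits = session_logits(sessions).to_numpy()
    n = len(logits)
    if n <= k:
        raise ValueError("need more sessions than sites")
    groups = sessions["site"].to_numpy()
    rss0 = float(np.sum((logits - logits.mean()) ** 2))
    rss1 = 0.0
    for s in sites:
        g = logits[groups == s]
        rss1 += float(np.sum((g - g.mean()) ** 2))
    if rss1 <= 0.0:
        if rss0 <= 0.0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = float("inf"), 0.0
    else:
        chi2 = n * np.log(rss0 / rss1)
        f_stat = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - k))
        p = float(stats.f.sf(f_stat, k - 1, n - k))
    return TestResult(
        method="Gaussian LRT, site factor on session logits",
        statistic=float(chi2),
        df=k - 1,
        p_value=p,
    )


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return [values[groups == g] for g in pd.unique(groups)]


def one_way_anova(values, groups) -> TestResult:
    """Classical one-way ANOVA F test, (k-1, N-k) df, unbalanced OK.

    A degenerate input with zero between- and within-group variance
    reports F = 0, p = 1 rather than failing.
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("one_way_anova needs >= 2 groups")
    n = sum(len(a) for a in arrays)
    k = len(arrays)
    if n - k < 1:
        raise ValueError("need residual degrees of freedom")
    all_vals = np.concatenate(arrays)
    if np.ptp(all_vals) == 0.0:
        return TestResult(method="one-way ANOVA", statistic=0.0, df=(k - 1, n - k), p_value=1.0)
    f_stat, p = stats.f_oneway(*arrays)
    return TestResult(
        method="one-way ANOVA", statistic=float(f_stat), df=(k - 1, n - k), p_value=float(p)
    )


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey-Kramer contrasts with family-wise adjusted p.

    Returns one row per pair: group1, group2, mean difference,
    adjusted p, confidence bounds and the rejection flag at ``alpha``.
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("tukey_hsd needs >= 2 groups")
    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups), alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    table = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "mean_diff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "lower": np.asarray(res.confint[:, 0], dtype=float),
            "upper": np.asarray(res.confint[:, 1], dtype=float),
            "significant": np.asarray(res.reject, dtype=bool),
        }
    )
    return table


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-based p-value
    (t = r * sqrt(df/(1-r^2)), df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("pearson_test needs n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("undefined correlation: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        method="Pearson correlation",
        statistic=float(r),
        df=len(x) - 2,
        p_value=float(p),
        estimate=float(r),
    )


class LinearFitResult:
    """Thin wrapper around a statsmodels OLS fit.

    Exposes coefficients, their standard errors, R^2 and the overall F
    test; the underlying results object stays reachable as ``.sm``.
    """

    def __init__(self, sm_results):
        self.sm = sm_results

    @property
    def params(self) -> pd.Series:
        return self.sm.params

    @property
    def bse(self) -> pd.Series:
        return self.sm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.sm.pvalues

    @property
    def r_squared(self) -> float:
        return float(self.sm.rsquared)

    @property
    def f_test(self) -> TestResult:
        f = float(self.sm.fvalue)
        p = float(self.sm.f_pvalue)
        if not np.isfinite(p):
            p = 0.0
        return TestResult(
            method="overall F",
            statistic=f,
            df=(int(self.sm.df_model), int(self.sm.df_resid)),
            p_value=max(min(p, 1.0), 0.0),
        )

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: max(float(v), P_FLOOR) for k, v in self.pvalues.items()},
            "r_squared": self.r_squared,
            "f": self.f_test.to_dict(),
        }


def linear_fit(data: pd.DataFrame, formula: str) -> LinearFitResult:
    """Ordinary least squares via a model formula, e.g.
    ``"seasonal_total_kj ~ one_way_distance_km"`` or
    ``"score ~ cost_z * sex"``.

    Raises on a rank-deficient design rather than silently dropping
    columns.
    """
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("singular design matrix")
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("need more observations than coefficients")
    return LinearFitResult(model.fit())


def _safe_pearson(x, y, method: str) -> TestResult:
    try:
        res = pearson_test(x, y)
        return TestResult(
            method=method, statistic=res.statistic, df=res.df, p_value=res.p_value,
            estimate=res.estimate,
        )
    except ValueError:
        return TestResult(
            method=method + " [undefined]", statistic=float("nan"), df=max(len(np.asarray(x)) - 2, 1),
            p_value=float("nan"),
        )


def hypothesis_panel(
    site_table: pd.DataFrame,
    cores_wide: pd.DataFrame,
    cost_column: str = "cost_kj",
    sample_level: bool = True,
) -> dict[str, TestResult]:
    """The four-way comparison of the cost hypothesis against resource
    partitioning.

    * ``cost``: site-level r between %F and wintering cost;
    * ``bottom``: r between %F and per-core bottom-layer AFDM density
      (each core paired with its site's %F when ``sample_level``);
    * ``top``: likewise for the top layer;
    * ``bottom_pct``: site-level r between %F and the mean bottom-layer
      share of AFDM.

    ``site_table`` needs columns site, pct_female, ``cost_column`` and
    bottom_pct_mean; ``cores_wide`` needs site, top_gm2, bottom_gm2.
    Degenerate inputs (for instance constant %F) yield flagged
    undefined results rather than exceptions.
    """
    needed = {"site", "pct_female", cost_column, "bottom_pct_mean"}
    missing = needed - set(site_table.columns)
    if missing:
        raise ValueError(f"site_table missing columns: {sorted(missing)}")
    if not {"site", "top_gm2", "bottom_gm2"} <= set(cores_wide.columns):
        raise ValueError("cores_wide missing site/top_gm2/bottom_gm2 columns")

    panel = {
        "cost": _safe_pearson(
            site_table["pct_female"], site_table[cost_column], "%F vs wintering cost (site-level)"
        ),
        "bottom_pct": _safe_pearson(
            site_table["pct_female"],
            site_table["bottom_pct_mean"],
            "%F vs bottom-layer AFDM share (site-level)",
        ),
    }
    if sample_level:
        merged = cores_wide.merge(site_table[["site", "pct_female"]], on="site", how="inner")
        for layer in ("bottom", "top"):
            col = f"{layer}_gm2"
            sub = merged.dropna(subset=[col])
            panel[layer] = _safe_pearson(
                sub["pct_female"], sub[col], f"%F vs {layer}-layer AFDM (sample-level)"
            )
    else:
        site_means = cores_wide.groupby("site")[["top_gm2", "bottom_gm2"]].mean().reset_index()
        merged = site_means.merge(site_table[["site", "pct_female"]], on="site", how="inner")
        for layer in ("bottom", "top"):
            panel[layer] = _safe_pearson(
                merged["pct_female"], merged[f"{layer}_gm2"],
                f"%F vs {layer}-layer AFDM (site-level)",
            )
    return panel
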