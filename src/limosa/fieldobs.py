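"""Sex-ratio scan sessions and abdominal-profile scores.

Flocks are scanned in single sessions yielding male/female tallies.
The unit of replication is the session, not the bird: each session's
female proportion is logit-transformed with the empirical adjustment
(y + 0.5)/(n + 1) — which keeps all-male and all-female scans finite
and maps an exactly even tally to logit 0 — and site-level estimates,
confidence intervals and bias tests operate on session logits.

Abdominal profile scores (APS) are an ordinal 1 (lean) to 5 (bulging)
index of visible energy stores, summarised per site and sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .result import TestResult

__all__ = [
    "adjusted_logit",
    "session_logits",
    "site_sex_ratio",
    "sex_ratio_table",
    "sex_bias_test",
    "validation_accuracy",
    "aps_summary",
    "read_counts",
    "read_aps",
]


def adjusted_logit(n_female, n_total):
    """Empirical logit of the female share: log(p/(1-p)) with
    p = (n_female + 0.5)/(n_total + 1).

    Antisymmetric under swapping the sexes; finite for one-sex sessions.
    Accepts scalars or arrays.
    """
    y = np.asarray(n_female, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_total must be >= 1")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("n_female must lie in [0, n_total]")
    p = (y + 0.5) / (n + 1.0)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def session_logits(sessions: pd.DataFrame) -> pd.Series:
    """Adjusted logit of the female share for each session row."""
    n_total = sessions["n_male"] + sessions["n_female"]
    return pd.Series(
        adjusted_logit(sessions["n_female"].to_numpy(), n_total.to_numpy()),
        index=sessions.index,
        name="logit_f",
    )


def site_sex_ratio(
    sessions: pd.DataFrame, confidence: float = 0.95, weight_by_size: bool = False
) -> dict:
    """Mean percentage of females at one site with a back-transformed
    t-interval on session logits.

    Sessions are equally weighted by default (the session is the random
    unit); ``weight_by_size=True`` weights each session logit by its
    flock size as a sensitivity variant.  With a single session the
    interval degenerates to the point and ``ci_defined`` is False.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    logits = session_logits(sessions).to_numpy()
    n_sessions = len(logits)
    sizes = (sessions["n_male"] + sessions["n_female"]).to_numpy(dtype=float)
    if weight_by_size:
        w = sizes / sizes.sum()
        mean = float(np.sum(w * logits))
        # weighted variance of the weighted mean
        var = float(np.sum(w * (logits - mean) ** 2) / max(n_sessions - 1, 1))
        se = np.sqrt(var)
    else:
        mean = float(np.mean(logits))
        se = float(np.std(logits, ddof=1) / np.sqrt(n_sessions)) if n_sessions > 1 else 0.0
    if n_sessions > 1:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n_sessions - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
    else:
        lo = hi = mean
    return {
        "site": str(sessions["site"].iloc[0]) if "site" in sessions else "",
        "pct_female": 100.0 * float(_inv_logit(mean)),
        "ci_low": 100.0 * float(_inv_logit(lo)),
        "ci_high": 100.0 * float(_inv_logit(hi)),
        "n_sessions": n_sessions,
        "n_birds": int(sizes.sum()),
        "ci_defined": n_sessions > 1,
    }


def sex_ratio_table(sessions: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-site sex-ratio estimates over all sites present."""
    rows = [
        site_sex_ratio(sessions[sessions["site"] == s], **kwargs)
        for s in sorted(sessions["site"].unique())
    ]
    return pd.DataFrame(rows)


def sex_bias_test(sessions: pd.DataFrame) -> TestResult:
    """Two-sided one-sample t-test of session logits against 0 (even
    sex ratio) for one site."""
    logits = session_logits(sessions).to_numpy()
    if len(logits) < 2:
        raise ValueError("sex_bias_test needs at least 2 sessions")
    if np.allclose(logits, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_1samp(logits, 0.0)
    return TestResult(
        method="one-sample t on session logits",
        statistic=float(t_stat),
        df=len(logits) - 1,
        p_value=float(p),
        estimate=100.0 * float(_inv_logit(np.mean(logits))),
    )


def validation_accuracy(n_correct: int, n_sightings: int) -> float:
    """Percentage of field sex assignments confirmed against marked
    birds of known sex, to one decimal."""
    if n_sightings < 1:
        raise ValueError("n_sightings must be >= 1")
    if not (0 <= n_correct <= n_sightings):
        raise ValueError("n_correct must lie in [0, n_sightings]")
    return round(100.0 * n_correct / n_sightings, 1)


def aps_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean abdominal profile score per site x sex, with group sizes.

    Groups without records are simply absent from the output.
    """
    bad = ~records["score"].isin([1, 2, 3, 4, 5])
    if bad.any():
        raise ValueError(f"APS scores outside 1-5: {sorted(records.loc[bad, 'score'].unique())}")
    out = (
        records.groupby(["site", "sex"], as_index=False)
        .agg(mean_score=("score", "mean"), n=("score", "size"))
        .sort_values(["site", "sex"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def read_counts(path) -> pd.DataFrame:
    """Read a count-session CSV (site, session_id, n_male, n_female)."""
    df = pd.read_csv(path)
    required = {"site", "session_id", "n_male", "n_female"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if ((df["n_male"] < 0) | (df["n_female"] < 0)).any():
        raise ValueError("counts must be >= 0")
    if ((df["n_male"] + df["n_female"]) < 1).any():
        raise ValueError("every session needs at least one bird")
    return df


def read_aps(path) -> pd.DataFrame:
    """Read an abdominal-profile CSV (site, sex, score)."""
    df = pd.read_csv(path)
    required = {"site", "sex", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"APS table missing columns: {sorted(missing)}")
    return df
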