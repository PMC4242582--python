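"""Common container for statistical test results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

__all__ = ["TestResult", "format_p", "P_FLOOR"]

#: p-values below this are reported as bounds ("< 1e-16"), never as 0.
P_FLOOR = 1e-16


def format_p(p: float) -> str:
    """Human-readable p-value; tiny values become a bound."""
    if p != p:  # NaN
        return "NA"
    if p < P_FLOOR:
        return f"< {P_FLOOR:g}"
    return f"{p:.4g}"


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom, p-value and (optionally) an effect
    estimate for one hypothesis test."""

    method: str
    statistic: float
    df: Union[float, tuple]
    p_value: float
    estimate: Optional[float] = None

    def __post_init__(self) -> None:
        p = self.p_value
        if p == p and not (0.0 <= p <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {p}")

    @property
    def p_label(self) -> str:
        return format_p(self.p_value)

    def to_dict(self) -> dict:
        def _num(x):
            if x is None or x != x or x in (float("inf"), float("-inf")):
                return None
            return float(x)

        df = list(self.df) if isinstance(self.df, tuple) else self.df
        p = self.p_value
        return {
            "method": self.method,
            "statistic": _num(self.statistic),
            "df": df,
            "p_value": _num(max(p, P_FLOOR)) if p == p else None,
            "p_label": self.p_label,
            "estimate": _num(self.estimate),
        }
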