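"""Two-sample t-test on delta-15N (per-mil) values from a 15N2 exposure
experiment.

An unchanged delta-15N after incubation under a 15N2 atmosphere means no
atmospheric N2 was fixed into the tissue; the test compares exposed versus
unexposed taproots.  Groups may be given as raw replicate values or as
summary statistics (mean, SD, n).  Welch's unequal-variance test is the
default; Student's pooled-variance test is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from scipy import stats

__all__ = [
    "IsotopeGroup",
    "TTestVariant",
    "TTestResult",
    "t_test",
    "significance_call",
]


class TTestVariant(str, Enum):
    WELCH = "welch"
    STUDENT = "student"


@dataclass(frozen=True)
class IsotopeGroup:
    """One treatment group, as replicates or as summary statistics."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: negative SD")

    @classmethod
    def from_replicates(cls, label: str, values: Sequence[float]) -> "IsotopeGroup":
        n = len(values)
        if n < 2:
            raise ValueError(f"group {label!r}: need >= 2 replicates, got {n}")
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        return cls(label=label, mean=mean, sd=math.sqrt(var), n=n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: TTestVariant


def t_test(
    g1: IsotopeGroup,
    g2: IsotopeGroup,
    variant: TTestVariant = TTestVariant.WELCH,
) -> TTestResult:
    """Two-sided two-sample t-test from group summaries.

    Degenerate case: if both SDs are zero and the means are equal, p is
    defined as 1 (no evidence of a difference); zero SDs with unequal means
    are an error.
    """
    variant = TTestVariant(variant)
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            df = g1.n + g2.n - 2
            return TTestResult(t=0.0, df=float(df), p=1.0, variant=variant)
        raise ValueError("both SDs are zero with unequal means: t is undefined")
    t, p = stats.ttest_ind_from_stats(
        g1.mean,
        g1.sd,
        g1.n,
        g2.mean,
        g2.sd,
        g2.n,
        equal_var=(variant is TTestVariant.STUDENT),
    )
    if variant is TTestVariant.STUDENT:
        df = float(g1.n + g2.n - 2)
    else:
        v1 = g1.sd**2 / g1.n
        v2 = g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TTestResult(t=float(t), df=df, p=float(p), variant=variant)


def significance_call(p: float, alpha: float = 0.05) -> str:
    """"significant" iff p is strictly below alpha."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return "significant" if p < alpha else "not_significant"
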