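"""Single-factor grading, compliance/exceedance rates and summary statistics.

Single-factor evaluation grades each indicator independently against the
grade scheme and, for a whole sample, takes the worst indicator's grade —
the conventional conservative screen that the fuzzy evaluation refines.

Exceedance defaults to failing Class III (the usual regulatory reference
for a drinking-water source); the class level is a parameter because
compliance is also reported against Classes I and II.  Every rate is
computed from integer counts over the data, and the counts are always
reported alongside the rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .indicators import INDICATORS, GradeScheme, SampleRecord

__all__ = [
    "single_factor_grade",
    "worst_factor_grade",
    "compliance_stats",
    "descriptive_stats",
    "grade_distribution",
    "GradeDistribution",
    "percent_display",
]


def percent_display(count: int, total: int, decimals: int = 1) -> float:
    """Percentage 100*count/total with half-up rounding, report display style."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(q, ROUND_HALF_UP))


def single_factor_grade(x: float, indicator: str, scheme: GradeScheme) -> tuple[int, bool]:
    """Grade one concentration; returns ``(grade, exceeds_V)``."""
    return scheme.grade_of(indicator, x)


def worst_factor_grade(sample: SampleRecord, scheme: GradeScheme) -> int:
    """Worst (highest-numbered) single-factor grade across the five indicators."""
    return max(scheme.grade_of(ind, sample.concentrations[ind])[0] for ind in INDICATORS)


def compliance_stats(samples: Sequence[SampleRecord], scheme: GradeScheme,
                     class_level: int = 3,
                     by: tuple[str, ...] = ("reach", "section")) -> pd.DataFrame:
    """Per-stratum, per-indicator compliance and exceedance at a class level.

    A sample complies for an indicator when its single-factor grade is at or
    better than ``class_level``.  Returns one row per (stratum, indicator)
    with columns ``n, n_pass, compliance_rate, exceedance_rate``.

    Raises on an empty sample list; strata are derived from the data, so an
    empty stratum cannot occur.
    """
    if not samples:
        raise ValueError("no samples: refusing to report 0/0 rates")
    rows = []
    for s in samples:
        key = tuple(getattr(s, attr) for attr in by)
        for ind in INDICATORS:
            g, _ = scheme.grade_of(ind, s.concentrations[ind])
            rows.append({**dict(zip(by, key)), "indicator": ind, "pass": g <= class_level})
    df = pd.DataFrame(rows)
    out = (
        df.groupby([*by, "indicator"], sort=False)["pass"]
        .agg(n="count", n_pass="sum")
        .reset_index()
    )
    out["compliance_rate"] = out["n_pass"] / out["n"]
    out["exceedance_rate"] = 1.0 - out["compliance_rate"]
    out["class_level"] = class_level
    return out


def descriptive_stats(samples: Sequence[SampleRecord] | pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/sd/median/CV per indicator (sample sd, ddof=1).

    CV = sd/mean; a zero mean leaves CV as NaN with ``cv_defined = False``.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples[list(INDICATORS)]
    else:
        df = pd.DataFrame([{ind: s.concentrations[ind] for ind in INDICATORS}
                           for s in samples])
    if len(df) < 2:
        raise ValueError("descriptive statistics need n >= 2")
    out = pd.DataFrame({
        "min": df.min(),
        "max": df.max(),
        "mean": df.mean(),
        "sd": df.std(ddof=1),
        "median": df.median(),
    })
    out["cv"] = np.where(out["mean"] != 0, out["sd"] / out["mean"], np.nan)
    # a constant column has sd 0 hence CV 0 (when the mean is nonzero)
    out["cv_defined"] = out["mean"] != 0
    out.index.name = "indicator"
    return out


@dataclass
class GradeDistribution:
    """Grade I..V counts for one stratum; percentages are always recomputed."""

    stratum: str
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, float]:
        return {g: percent_display(c, self.total) for g, c in self.counts.items()}

    def to_series(self) -> pd.Series:
        return pd.Series({f"grade_{g}": self.counts.get(g, 0) for g in range(1, 6)},
                         name=self.stratum)


def grade_distribution(grades: Iterable[int], stratum: str = "all") -> GradeDistribution:
    """Tally grades I..V; raises on empty input."""
    grades = list(grades)
    if not grades:
        raise ValueError("no grades to tally")
    counts = {g: 0 for g in range(1, 6)}
    for g in grades:
        if g not in counts:
            raise ValueError(f"grade out of range: {g}")
        counts[g] += 1
    return GradeDistribution(stratum=stratum, counts=counts)
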