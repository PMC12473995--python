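"""Five-grade fuzzy membership functions over concentration.

Each indicator gets one membership function per grade: a semi-trapezoid
saturating toward clean values for grade I, a semi-trapezoid saturating
toward polluted values for grade V, and triangles for grades II-IV whose
feet sit at the neighbouring grades' apexes.  The apex of grade k is the
midpoint of grade k's concentration interval (grade I of a cost indicator
uses the midpoint of [0, t1]; DO's unbounded grade-I apex is its regulatory
bound).  This construction makes the five functions a partition of unity
between the outer apexes, with full saturation outside them, so every
concentration yields a membership vector summing to exactly 1 with at most
two nonzero entries.

The apex is called ``m_apex`` where it appears as a parameter, to keep it
distinct from m = number of indicators used elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indicators import INDICATORS, POLARITY, GradeScheme, SampleRecord

__all__ = [
    "MembershipFunctionSet",
    "build_membership_functions",
    "build_all_membership_functions",
    "membership_vector",
    "membership_matrix",
]


@dataclass(frozen=True)
class MembershipFunctionSet:
    """The five grade membership functions of one indicator.

    ``apexes`` lists the grade apexes c_1..c_5 in grade order: strictly
    increasing for cost indicators, strictly decreasing for DO.
    """

    indicator: str
    polarity: str
    apexes: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        d = np.diff(self.apexes)
        ok = np.all(d > 0) if self.polarity == "cost" else np.all(d < 0)
        if not ok:
            raise ValueError(f"{self.indicator}: apexes not monotone: {self.apexes}")


def build_membership_functions(scheme: GradeScheme, indicator: str) -> MembershipFunctionSet:
    """Derive the apex sequence for one indicator from its grade intervals."""
    t = scheme.thresholds[indicator]
    pol = POLARITY[indicator]
    if pol == "cost":
        apexes = (t[0] / 2.0,) + tuple((t[k - 1] + t[k]) / 2.0 for k in range(1, 5))
    else:
        # grade I is unbounded above; its apex is the regulatory bound itself
        apexes = (t[0],) + tuple((t[k - 1] + t[k]) / 2.0 for k in range(1, 5))
    return MembershipFunctionSet(indicator=indicator, polarity=pol, apexes=apexes)


def build_all_membership_functions(scheme: GradeScheme) -> dict[str, MembershipFunctionSet]:
    return {ind: build_membership_functions(scheme, ind) for ind in INDICATORS}


def _hat_basis(x: float, apexes: np.ndarray) -> np.ndarray:
    """Piecewise-linear hat functions over an increasing apex sequence."""
    r = np.zeros(len(apexes))
    if x <= apexes[0]:
        r[0] = 1.0
    elif x >= apexes[-1]:
        r[-1] = 1.0
    else:
        k = int(np.searchsorted(apexes, x))  # apexes[k-1] < x <= apexes[k]
        t = (x - apexes[k - 1]) / (apexes[k] - apexes[k - 1])
        r[k - 1] = 1.0 - t
        r[k] = t
    return r


def membership_vector(x: float, fns: MembershipFunctionSet) -> np.ndarray:
    """Membership degrees of a concentration in grades I..V.

    Sums to 1 with at most two nonzero entries; concentrations outside the
    outer apexes saturate fully on grade I or grade V.
    """
    if x < 0:
        raise ValueError(f"{fns.indicator}: negative concentration {x}")
    apexes = np.asarray(fns.apexes, dtype=float)
    if fns.polarity == "benefit":
        # DO mirrors a cost indicator under x -> -x
        return _hat_basis(-x, -apexes)
    return _hat_basis(x, apexes)


def membership_matrix(sample: SampleRecord,
                      fns: dict[str, MembershipFunctionSet]) -> np.ndarray:
    """Stack the per-indicator membership vectors into the m x 5 matrix R."""
    rows = []
    for ind in INDICATORS:
        if ind not in fns:
            raise ValueError(f"no membership functions for indicator {ind}")
        rows.append(membership_vector(sample.concentrations[ind], fns[ind]))
    return np.vstack(rows)
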