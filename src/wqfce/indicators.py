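"""Indicator definitions, grade schemes and measurement-table validation.

Five indicators are evaluated, all in mg/L: dissolved oxygen (DO, a benefit
indicator — higher is better) and four pollutants (TN, NH3-N, TP, COD_Mn,
cost indicators — lower is better).  Concentrations are graded into the five
Chinese surface-water classes I (cleanest) to V (worst).  Two built-in grade
schemes are provided: the GB 3838-2002 national standard and a customized
scheme with tightened COD_Mn and DO bounds for a drinking-water reservoir.

Interval convention: for cost indicators grade k covers ``(t_{k-1}, t_k]``
with grade I closed at its regulatory bound (``x <= t_1``); for DO the
intervals mirror downward with grade I at ``x >= t_1``.  Values beyond the
grade-V outer bound are still classified as grade V but carry an
``exceeds_V`` flag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INDICATORS",
    "POLARITY",
    "GradeScheme",
    "SampleRecord",
    "DataMatrix",
    "load_scheme",
    "validate_samples",
    "samples_from_dataframe",
]

#: canonical indicator order, fixed for every matrix in the package
INDICATORS: tuple[str, ...] = ("DO", "TN", "NH3N", "TP", "CODMn")

#: direction of each indicator ("benefit": higher is better)
POLARITY: Mapping[str, str] = {
    "DO": "benefit",
    "TN": "cost",
    "NH3N": "cost",
    "TP": "cost",
    "CODMn": "cost",
}

GRADES = (1, 2, 3, 4, 5)

# Grade boundary values t_1..t_5 per indicator.  For cost indicators the
# sequence increases (grade k = (t_{k-1}, t_k], grade I = [0, t_1]); for DO it
# decreases (grade I = [t_1, inf), grade k = (t_k, t_{k-1}]).
_GB3838 = {
    "DO": (7.5, 6.5, 6.0, 3.0, 2.0),
    "TN": (0.2, 0.5, 1.0, 1.5, 2.0),
    "NH3N": (0.15, 0.5, 1.0, 1.5, 2.0),
    "TP": (0.01, 0.025, 0.05, 0.1, 0.2),
    "CODMn": (2.0, 4.0, 6.0, 10.0, 15.0),
}

_CUSTOMIZED = {
    "DO": (7.5, 6.5, 6.0, 5.5, 4.5),
    "TN": (0.2, 0.5, 1.0, 1.5, 2.0),
    "NH3N": (0.15, 0.5, 1.0, 1.5, 2.0),
    "TP": (0.01, 0.025, 0.05, 0.1, 0.2),
    "CODMn": (1.0, 2.0, 3.0, 4.0, 5.0),
}

_BUILTIN = {"gb3838": _GB3838, "customized": _CUSTOMIZED}


class SchemeError(ValueError):
    """Raised for unknown or non-monotone grade schemes."""


@dataclass(frozen=True)
class GradeScheme:
    """Grade boundary table for the five indicators.

    Parameters
    ----------
    scheme_id : str
        Identifier (``"gb3838"``, ``"customized"`` or a user label).
    thresholds : mapping
        Per indicator, the five grade boundary values ``t_1..t_5``
        (increasing for cost indicators, decreasing for DO).
    """

    scheme_id: str
    thresholds: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for ind in INDICATORS:
            if ind not in self.thresholds:
                raise SchemeError(f"scheme {self.scheme_id!r}: missing indicator {ind}")
            t = tuple(float(v) for v in self.thresholds[ind])
            if len(t) != 5:
                raise SchemeError(f"{ind}: expected 5 boundary values, got {len(t)}")
            diffs = np.diff(t)
            if POLARITY[ind] == "cost" and not np.all(diffs > 0):
                raise SchemeError(f"{ind}: cost thresholds must strictly increase: {t}")
            if POLARITY[ind] == "benefit" and not np.all(diffs < 0):
                raise SchemeError(f"{ind}: benefit thresholds must strictly decrease: {t}")
            object.__setattr__(self, "thresholds", {**self.thresholds, ind: t})

    # -- interval views ---------------------------------------------------
    def intervals(self, indicator: str) -> list[tuple[float, float]]:
        """(lower, upper) endpoints of grades I..V on the concentration axis.

        Grade I of a cost indicator is reported as ``(0, t_1)``; DO's grade I
        is ``(t_1, inf)``.  Adjacent intervals share endpoints (no gaps).
        """
        t = self.thresholds[indicator]
        if POLARITY[indicator] == "cost":
            lowers = (0.0,) + t[:4]
            return list(zip(lowers, t))
        uppers = (np.inf,) + t[:4]
        return [(lo, up) for lo, up in zip(t, uppers)]

    def grade_of(self, indicator: str, x: float) -> tuple[int, bool]:
        """Classify a concentration; returns ``(grade, exceeds_V)``."""
        if x < 0:
            raise ValueError(f"{indicator}: negative concentration {x}")
        t = self.thresholds[indicator]
        if POLARITY[indicator] == "cost":
            for k, bound in enumerate(t, start=1):
                if x <= bound:
                    return k, False
            return 5, True
        if x >= t[0]:
            return 1, False
        for k, bound in enumerate(t[1:], start=2):
            if x > bound:
                return k, False
        return 5, True

    def class_bound(self, indicator: str, class_level: int) -> float:
        """Regulatory bound of a class (upper for cost indicators, lower for DO)."""
        return self.thresholds[indicator][class_level - 1]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "indicators": {
                ind: {
                    "polarity": POLARITY[ind],
                    "unit": "mg/L",
                    "bounds": list(self.thresholds[ind]),
                }
                for ind in INDICATORS
            },
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GradeScheme":
        thresholds = {ind: tuple(spec["bounds"]) for ind, spec in d["indicators"].items()}
        return cls(scheme_id=d["scheme_id"], thresholds=thresholds)

    @classmethod
    def from_yaml(cls, text: str) -> "GradeScheme":
        return cls.from_dict(yaml.safe_load(text))


def load_scheme(scheme_id: str) -> GradeScheme:
    """Load a built-in grade scheme, or parse a user YAML/JSON config path.

    Raises
    ------
    SchemeError
        For an unknown id or a config with non-monotone thresholds.
    """
    if scheme_id in _BUILTIN:
        return GradeScheme(scheme_id=scheme_id, thresholds=_BUILTIN[scheme_id])
    try:
        with open(scheme_id) as fh:
            return GradeScheme.from_yaml(fh.read())
    except OSError as exc:
        raise SchemeError(
            f"unknown scheme {scheme_id!r}: not a built-in "
            f"({', '.join(sorted(_BUILTIN))}) and not a readable config path"
        ) from exc


@dataclass
class SampleRecord:
    """One monitoring site: metadata plus the five concentrations (mg/L).

    A concentration of 0.0 denotes a below-detection reading.
    """

    site_id: str
    concentrations: Mapping[str, float]
    reach: str = "main"  # "main" | "tributary"
    section: str = "none"  # "upstream" | "midstream" | "downstream" | "none"

    def __post_init__(self) -> None:
        for ind in INDICATORS:
            if ind not in self.concentrations:
                raise ValueError(f"site {self.site_id}: missing indicator {ind}")
            v = self.concentrations[ind]
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"site {self.site_id}: invalid {ind} value {v}")


@dataclass
class DataMatrix:
    """Rectangular n-sites x m-indicators concentration grid.

    ``values[i, j]`` is site i's concentration of ``columns[j]``; column order
    is the canonical indicator order and is recorded explicitly.
    """

    values: np.ndarray
    site_ids: list[str]
    columns: tuple[str, ...] = INDICATORS
    meta: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "site_id", self.site_ids)
        if self.meta is not None:
            df = pd.concat([df, self.meta.reset_index(drop=True)], axis=1)
        return df


def samples_from_dataframe(df: pd.DataFrame) -> list[SampleRecord]:
    """Build sample records from a table with columns
    ``site_id, [reach, section,] DO, TN, NH3N, TP, CODMn``."""
    missing = [c for c in ("site_id", *INDICATORS) if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleRecord(
                site_id=str(row.site_id),
                reach=getattr(row, "reach", "main"),
                section=getattr(row, "section", "none"),
                concentrations={ind: float(getattr(row, ind)) for ind in INDICATORS},
            )
        )
    return out


def validate_samples(samples: Sequence[SampleRecord] | Iterable[SampleRecord]) -> DataMatrix:
    """Validate sample records and assemble the rectangular data matrix.

    Rejects empty input and (via ``SampleRecord``) negative or missing
    concentrations, naming the offending site and indicator.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples provided")
    values = np.array(
        [[s.concentrations[ind] for ind in INDICATORS] for s in samples], dtype=float
    )
    meta = pd.DataFrame(
        {"reach": [s.reach for s in samples], "section": [s.section for s in samples]}
    )
    return DataMatrix(
        values=values, site_ids=[s.site_id for s in samples], columns=INDICATORS, meta=meta
    )
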