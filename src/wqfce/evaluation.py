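"""Composite fuzzy evaluation, ambiguity flagging and the EWQI comparator.

The composite membership vector of a sample is B = W x R: b_k = sum_j w_j
r_jk, the weighted share of evidence for grade k.  The grade is the argmax
of B (maximum membership principle), breaking exact ties toward the worse
grade — the conservative call for a drinking-water source.

Grade calls with a thin margin are unreliable: after normalizing B to sum 1,
a difference below 0.2 between the top two memberships flags the assessment
as ambiguous.

EWQI: an entropy-weighted water quality index used as a scalar comparator.
Each cost indicator contributes a rating q_j = 100 * C_j / S_j, where S_j is
the indicator's Class III regulatory bound; DO contributes the inverted
ratio 100 * S_j / C_j (capped, so a near-zero DO cannot blow up the score).
EWQI = sum_j w_j q_j; class bands default to I <= 50 < II <= 100 < III
<= 150 < IV <= 200 < V.  This index is a reconstruction of a standard form;
its bands are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import WeightVector
from .indicators import INDICATORS, POLARITY, GradeScheme, SampleRecord

__all__ = [
    "EvaluationResult",
    "evaluate_sample",
    "flag_ambiguity",
    "ewqi",
    "compare_methods",
    "DEFAULT_AMBIGUITY_THRESHOLD",
    "DEFAULT_EWQI_BANDS",
]

DEFAULT_AMBIGUITY_THRESHOLD = 0.2
DEFAULT_EWQI_BANDS = (50.0, 100.0, 150.0, 200.0)
DEFAULT_DO_RATING_CAP = 500.0


@dataclass
class EvaluationResult:
    """Composite evaluation of one sample."""

    site_id: str
    composite: np.ndarray          # B, raw weighted memberships b_1..b_5
    normalized: np.ndarray         # B / sum(B)
    grade: int                     # 1..5, maximum membership with worse-grade ties
    margin: float                  # top-two difference of the normalized vector
    ambiguous: bool


def _argmax_worst(b: np.ndarray) -> int:
    """Index of the maximum, preferring the highest (worst) grade on ties."""
    rev = b[::-1]
    return len(b) - 1 - int(np.argmax(rev))


def flag_ambiguity(composite: np.ndarray,
                   threshold: float = DEFAULT_AMBIGUITY_THRESHOLD) -> tuple[bool, float]:
    """Normalize B and test whether the top-two membership gap is below threshold.

    Returns ``(ambiguous, margin)`` where margin = max - second max of the
    normalized vector.
    """
    b = np.asarray(composite, dtype=float)
    total = b.sum()
    if total <= 0:
        raise ValueError("composite vector sums to zero; cannot normalize")
    p = np.sort(b / total)[::-1]
    margin = float(p[0] - p[1])
    return margin < threshold, margin


def evaluate_sample(R: np.ndarray, W: WeightVector | np.ndarray,
                    site_id: str = "",
                    ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
                    ) -> EvaluationResult:
    """Compose B = W x R and assign the grade by maximum membership."""
    w = W.weights if isinstance(W, WeightVector) else np.asarray(W, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.shape[0] != w.shape[0]:
        raise ValueError(f"dimension mismatch: R has {R.shape[0]} rows, W has {w.shape[0]}")
    b = w @ R
    ambiguous, margin = flag_ambiguity(b, ambiguity_threshold)
    return EvaluationResult(
        site_id=site_id,
        composite=b,
        normalized=b / b.sum(),
        grade=_argmax_worst(b) + 1,
        margin=margin,
        ambiguous=ambiguous,
    )


def ewqi(sample: SampleRecord, W: WeightVector | np.ndarray, scheme: GradeScheme,
         class_bands: tuple[float, ...] = DEFAULT_EWQI_BANDS,
         do_rating_cap: float = DEFAULT_DO_RATING_CAP) -> tuple[float, int]:
    """Entropy-weighted water quality index of one sample.

    Returns ``(score, grade)``.  A sample with every indicator exactly at its
    Class III bound scores 100 by construction.
    """
    w = W.weights if isinstance(W, WeightVector) else np.asarray(W, dtype=float)
    score = 0.0
    for j, ind in enumerate(INDICATORS):
        c = sample.concentrations[ind]
        s = scheme.class_bound(ind, 3)
        if POLARITY[ind] == "cost":
            q = 100.0 * c / s
        else:
            q = do_rating_cap if c == 0 else min(100.0 * s / c, do_rating_cap)
        score += w[j] * q
    grade = 1 + int(np.searchsorted(np.asarray(class_bands), score, side="left"))
    return float(score), min(grade, 5)


def compare_methods(fce_grades: pd.Series | dict,
                    ewqi_grades: pd.Series | dict) -> dict:
    """Site-by-site agreement between the fuzzy evaluation and the EWQI.

    Returns a dict with the per-site grade pairs, the 5x5 confusion matrix
    (fuzzy grade in rows, EWQI grade in columns), the discordant site list
    and the two mean grades.
    """
    f = pd.Series(fce_grades)
    e = pd.Series(ewqi_grades)
    if set(f.index) != set(e.index):
        raise ValueError("site sets differ between the two methods")
    e = e.reindex(f.index)
    pairs = pd.DataFrame({"fce": f, "ewqi": e})
    confusion = pd.crosstab(pairs["fce"], pairs["ewqi"]).reindex(
        index=range(1, 6), columns=range(1, 6), fill_value=0
    )
    discordant = pairs[pairs["fce"] != pairs["ewqi"]].copy()
    discordant["difference"] = discordant["fce"] - discordant["ewqi"]
    discordant = discordant.sort_values("difference", key=abs, ascending=False)
    return {
        "pairs": pairs,
        "confusion": confusion,
        "discordant": discordant,
        "n_discordant": int(len(discordant)),
        "mean_grade_fce": float(f.mean()),
        "mean_grade_ewqi": float(e.mean()),
    }
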