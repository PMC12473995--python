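"""Source-resolved annual pollutant-discharge accounting.

An emission ledger lists (source type, subcategory, pollutant, tonnes/year)
records for the catchment — e.g. livestock COD_Mn, urban domestic TN.  The
module aggregates them into per-pollutant totals, per-source-type subtotals
and per-subcategory contribution ratios.  An absent entry (printed "/" in
inventory tables, meaning not assessed) is tracked as missing, never as
zero: it is excluded from sums and from ratio denominators.

A packaged inventory for the Wan'an Reservoir catchment ships with the
module (``load_wanan_inventory``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EmissionRecord",
    "EmissionSummary",
    "SOURCE_TYPES",
    "EMISSION_POLLUTANTS",
    "read_inventory",
    "load_wanan_inventory",
    "aggregate",
    "subtotal_by_source_type",
    "contribution_ratios",
]

SOURCE_TYPES = ("industrial", "agricultural", "domestic", "centralized")
EMISSION_POLLUTANTS = ("CODMn", "NH3N", "TN", "TP")
RATIO_TOL = 1e-12


@dataclass(frozen=True)
class EmissionRecord:
    """One (source, pollutant) discharge figure in tonnes/year; ``None`` = not assessed."""

    source_type: str
    subcategory: str
    pollutant: str
    amount: float | None

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source type {self.source_type!r}")
        if self.pollutant not in EMISSION_POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        if self.amount is not None and self.amount < 0:
            raise ValueError(f"negative emission amount {self.amount}")


@dataclass
class EmissionSummary:
    """Aggregated ledger: totals, source-type subtotals, subcategory ratios."""

    totals: dict[str, float]                       # pollutant -> t/a
    by_source_type: pd.DataFrame                   # source_type x pollutant
    by_subcategory: pd.DataFrame                   # subcategory x pollutant
    ratios: dict[str, dict[str, float]]            # pollutant -> subcategory share


def read_inventory(path) -> list[EmissionRecord]:
    """Read an inventory CSV; '/' or blank amounts become not-assessed."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["amount_t_per_a"].strip()
            amount = None if raw in ("", "/") else float(raw)
            records.append(EmissionRecord(
                source_type=row["source_type"].strip(),
                subcategory=row["subcategory"].strip(),
                pollutant=row["pollutant"].strip(),
                amount=amount,
            ))
    return records


def load_wanan_inventory() -> list[EmissionRecord]:
    """The packaged Wan'an Reservoir annual discharge inventory."""
    ref = resources.files("wqfce").joinpath("data/wanan_inventory.csv")
    with resources.as_file(ref) as path:
        return read_inventory(path)


def _frame(records: Sequence[EmissionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_type": r.source_type,
                "subcategory": r.subcategory,
                "pollutant": r.pollutant,
                "amount": r.amount,
            }
            for r in records
            if r.amount is not None
        ]
    )


def aggregate(records: Iterable[EmissionRecord]) -> EmissionSummary:
    """Totals, subtotals and contribution ratios from a ledger."""
    records = list(records)
    df = _frame(records)
    if df.empty:
        empty = pd.DataFrame(columns=list(EMISSION_POLLUTANTS))
        return EmissionSummary(totals={}, by_source_type=empty,
                               by_subcategory=empty.copy(), ratios={})
    by_type = df.pivot_table(index="source_type", columns="pollutant",
                             values="amount", aggfunc="sum")
    by_sub = df.pivot_table(index="subcategory", columns="pollutant",
                            values="amount", aggfunc="sum")
    totals = df.groupby("pollutant")["amount"].sum().to_dict()
    ratios = {}
    for pol, total in totals.items():
        if total > 0:
            col = by_sub[pol].dropna()
            ratios[pol] = (col / total).to_dict()
    return EmissionSummary(totals=totals, by_source_type=by_type,
                           by_subcategory=by_sub, ratios=ratios)


def subtotal_by_source_type(records: Iterable[EmissionRecord],
                            source_type: str, pollutant: str) -> float | None:
    """Sum over matching records; ``None`` when nothing was assessed."""
    if source_type not in SOURCE_TYPES:
        raise ValueError(f"unknown source type {source_type!r}")
    if pollutant not in EMISSION_POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    amounts = [r.amount for r in records
               if r.source_type == source_type and r.pollutant == pollutant
               and r.amount is not None]
    return sum(amounts) if amounts else None


def contribution_ratios(records: Iterable[EmissionRecord] | EmissionSummary,
                        pollutant: str) -> dict[str, float]:
    """Subcategory shares of one pollutant's total; shares sum to 1."""
    summary = records if isinstance(records, EmissionSummary) else aggregate(list(records))
    if pollutant not in summary.ratios:
        raise ValueError(f"no assessed emissions for pollutant {pollutant!r}")
    return summary.ratios[pollutant]
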