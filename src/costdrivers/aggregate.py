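"""Per-driver aggregate coefficients and the warranted/unwarranted partition.

Each driver's aggregate coefficient is the sum of absolute fitted
coefficients over its design columns.  Because the columns within a group
are pairwise uncorrelated after the PCA step, the absolute values add without
double counting, and the aggregate is a meaningful summary of the group's
total pull on cost variability.  A driver's *percentage of total variability*
is its aggregate divided by the sum of aggregates over all drivers, times
100; the predictable and non-predictable subtotals of those shares always sum
to exactly 100 and the non-predictable subtotal is the upper bound on
potentially unwarranted (waste-related) variability.

All columns carry unit variance when the model is fitted, so absolute
coefficients are directly comparable between singleton continuous drivers
and multi-component categorical groups; this standardized scale is the
default.  An alternative range scaling (|beta| times the design-column range)
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import GroupedDesign
from .roster import PredictorSpec


@dataclass
class DriverAggregate:
    name: str
    predictable: bool
    aggregate: float
    share: float | None           # percent of total; None for the null model
    ci: tuple | None = None       # optional (lo, hi) on the aggregate


@dataclass
class AggregateReport:
    drivers: list
    subtotal_predictable: float | None
    subtotal_nonpredictable: float | None
    null_model: bool
    orthogonalized: bool
    warning: str | None = None
    scaling: str = "standardized"

    def driver(self, name: str) -> DriverAggregate:
        return next(d for d in self.drivers if d.name == name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "driver": d.name,
            "predictable": d.predictable,
            "aggregate": d.aggregate,
            "share_pct": d.share,
            "ci_low": None if d.ci is None else d.ci[0],
            "ci_high": None if d.ci is None else d.ci[1],
        } for d in self.drivers]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "null_model": self.null_model,
            "orthogonalized": self.orthogonalized,
            "warning": self.warning,
            "scaling": self.scaling,
            "subtotal_predictable_pct": self.subtotal_predictable,
            "subtotal_nonpredictable_pct": self.subtotal_nonpredictable,
            "drivers": [
                {"name": d.name, "predictable": d.predictable,
                 "aggregate": d.aggregate, "share_pct": d.share,
                 "ci": None if d.ci is None else list(d.ci)}
                for d in self.drivers
            ],
        }


def aggregate_coefficients(beta: np.ndarray, design: GroupedDesign,
                           roster: Sequence[PredictorSpec],
                           scaling: str = "standardized",
                           ci: Mapping | None = None) -> AggregateReport:
    """Build the per-driver aggregate report from any coefficient vector.

    Shared by the penalized and unpenalized arms so both tables use the
    identical statistic.  Non-finite coefficients (columns an OLS rank check
    dropped) contribute zero.
    """
    flags = {p.name: p.predictable for p in roster}
    missing = [g for g in design.groups if g not in flags]
    if missing:
        raise ValueError(f"drivers in design absent from roster: {missing}")
    if scaling not in ("standardized", "range"):
        raise ValueError(f"unknown scaling {scaling!r}")

    beta = np.nan_to_num(np.asarray(beta, dtype=float), nan=0.0,
                         posinf=0.0, neginf=0.0)
    aggs: dict = {}
    for name, idx in design.groups.items():
        idx = np.asarray(idx, int)
        mag = np.abs(beta[idx])
        if scaling == "range" and len(idx):
            B = design.matrix[:, idx]
            mag = mag * (B.max(axis=0) - B.min(axis=0))
        aggs[name] = float(mag.sum())

    total = sum(aggs.values())
    null_model = total <= 0.0
    drivers = []
    sub_p = sub_np = None
    if null_model:
        for name in design.groups:
            drivers.append(DriverAggregate(name, flags[name], 0.0, None,
                                           None if ci is None else tuple(ci.get(name)) if name in ci else None))
    else:
        sub_p = sub_np = 0.0
        for name in design.groups:
            share = 100.0 * aggs[name] / total
            if flags[name]:
                sub_p += share
            else:
                sub_np += share
            drivers.append(DriverAggregate(
                name, flags[name], aggs[name], share,
                None if ci is None or name not in ci else tuple(ci[name])))

    warning = None
    if not design.orthogonalized:
        warning = ("design groups are not orthogonalized; summing absolute "
                   "coefficients may double-count correlated within-group columns")
    return AggregateReport(drivers=drivers, subtotal_predictable=sub_p,
                           subtotal_nonpredictable=sub_np, null_model=null_model,
                           orthogonalized=design.orthogonalized, warning=warning,
                           scaling=scaling)


def aggregate(fit_result, design: GroupedDesign, roster: Sequence[PredictorSpec],
              scaling: str = "standardized", ci: Mapping | None = None) -> AggregateReport:
    """Aggregate report for a sparse group lasso fit."""
    return aggregate_coefficients(fit_result.beta, design, roster,
                                  scaling=scaling, ci=ci)


def warranted_split(report: AggregateReport) -> tuple[float, float]:
    """(predictable %, non-predictable %) subtotals of the share decomposition.

    The non-predictable subtotal is the upper bound on unwarranted (waste-
    related) cost variability.  Raises on a null-model report.
    """
    if report.null_model:
        raise ValueError("null model: all coefficients are zero, shares undefined")
    return float(report.subtotal_predictable), float(report.subtotal_nonpredictable)
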