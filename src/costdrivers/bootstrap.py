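"""Bootstrap confidence intervals for the per-driver aggregate coefficients.

Nonparametric pairs bootstrap: admission rows are resampled with
replacement, the entire pipeline (imputation, encoding, per-group PCA,
standardization, sparse group lasso fit) is re-run on every replicate, and
percentile intervals are taken over the replicate aggregates.  The penalty
(lambda*, alpha*) is held fixed by default; ``refit_lambda=True`` re-runs the
cross-validated selection inside every replicate as a sensitivity analysis.
Percentile intervals after model selection are approximate — selection events
(a group entering or leaving the active set) are part of the resampled
variability, which is the pragmatic choice for a penalized pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import sgl
from .aggregate import aggregate_coefficients
from .preprocess import fit_design
from .roster import PredictorSpec


@dataclass
class BootstrapConfig:
    B: int = 200
    level: float = 0.95
    seed: int = 0
    refit_lambda: bool = False

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        needed = math.ceil(1.0 / ((1.0 - self.level) / 2.0))
        if self.B < needed:
            raise ValueError(
                f"B={self.B} too small for level {self.level}; need at least {needed}")


@dataclass
class BootstrapResult:
    intervals: dict            # driver -> (lo, hi) on the aggregate
    replicates: pd.DataFrame   # B rows, one column per driver
    level: float
    penalty: sgl.PenaltyConfig


def bootstrap_aggregates(records: pd.DataFrame, roster: Sequence[PredictorSpec],
                         penalty: sgl.PenaltyConfig, bcfg: BootstrapConfig,
                         retain: float | None = 0.995, outcome: str = "cost",
                         add_squares: Sequence[str] = (), tol: float = 1e-6,
                         max_iter: int = 5000, cv_kwargs: dict | None = None
                         ) -> BootstrapResult:
    """Percentile intervals for every driver aggregate via pairs bootstrap."""
    from .selection import cross_validate  # local import avoids a cycle

    rng = np.random.default_rng(bcfg.seed)
    n = len(records)
    rows: list[dict] = []
    for _ in range(bcfg.B):
        take = rng.integers(0, n, size=n)
        rec_b = records.iloc[take].reset_index(drop=True)
        pen = penalty
        if bcfg.refit_lambda:
            cv = cross_validate(rec_b, roster, retain=retain, outcome=outcome,
                                add_squares=add_squares,
                                **(cv_kwargs or {"alpha_grid": (penalty.alpha,),
                                                 "n_lambda": 20, "k": 5,
                                                 "seed": int(rng.integers(2**31))}))
            pen = sgl.PenaltyConfig(cv.best[1], cv.best[0], penalty.group_weights)
        design, _ = fit_design(rec_b, roster, retain=retain, add_squares=add_squares)
        y = rec_b[outcome].to_numpy(dtype=float)
        fr = sgl.fit(design, y, pen, tol=tol, max_iter=max_iter,
                     record_objective=False)
        rep = aggregate_coefficients(fr.beta, design, roster)
        rows.append({d.name: d.aggregate for d in rep.drivers})

    reps = pd.DataFrame(rows)
    lo_q = (1.0 - bcfg.level) / 2.0
    intervals = {
        col: (float(np.quantile(reps[col], lo_q)),
              float(np.quantile(reps[col], 1.0 - lo_q)))
        for col in reps.columns
    }
    return BootstrapResult(intervals=intervals, replicates=reps,
                           level=bcfg.level, penalty=penalty)
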