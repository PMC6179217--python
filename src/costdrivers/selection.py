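"""Cross-validated selection of the penalty parameters (lambda, alpha).

Rows are partitioned into k folds by a seeded shuffle.  For every fold the
whole preprocessing transform (imputation values, level sets, per-group PCA,
scalings) is refit on the training rows only and applied, frozen, to the
held-out rows — the no-leakage contract.  The lambda grid is log-spaced from
lambda_max of the full-data design down to lambda_max * lam_min_ratio,
separately per alpha; within a fold the fits are warm-started from large to
small lambda.  The selected pair minimizes the mean held-out squared error,
with ties broken toward larger lambda and then larger alpha (the sparser
model).

The selected lambda is tied to this implementation's 1/(2 n) loss scaling
and unit-variance column standardization; penalty values are not transferable
across differently scaled formulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import sgl
from .preprocess import apply_transform, fit_design
from .roster import PredictorSpec

LOSS_SCALING = "rss / (2 * n_rows); columns standardized to unit variance"


@dataclass
class CVResult:
    alpha_grid: np.ndarray
    lam_grid: np.ndarray      # shape (n_alpha, n_lambda), decreasing per row
    mean_error: np.ndarray    # shape (n_alpha, n_lambda)
    se_error: np.ndarray      # shape (n_alpha, n_lambda)
    best: tuple               # (alpha*, lambda*) at the error minimum
    best_index: tuple         # (alpha row, lambda column)
    best_1se: tuple           # largest lambda within 1 SE of the minimum (same alpha)
    best_1se_index: tuple
    fold_seed: int
    k: int
    loss_scaling: str = LOSS_SCALING

    def curve(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """(lam, mean_error) slice for one alpha value."""
        rows = np.flatnonzero(np.isclose(self.alpha_grid, alpha))
        if len(rows) == 0:
            raise ValueError(f"alpha {alpha} not in the searched grid")
        i = int(rows[0])
        return self.lam_grid[i], self.mean_error[i]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.alpha_grid):
            for j in range(self.lam_grid.shape[1]):
                recs.append({"alpha": float(a), "lam": float(self.lam_grid[i, j]),
                             "mean_error": float(self.mean_error[i, j]),
                             "se_error": float(self.se_error[i, j])})
        return pd.DataFrame(recs)


def cross_validate(records: pd.DataFrame, roster: Sequence[PredictorSpec],
                   retain: float | None = 0.995,
                   alpha_grid: Sequence[float] = (0.05, 0.15, 0.5, 0.85, 0.95),
                   n_lambda: int = 50, k: int = 10, seed: int = 0,
                   outcome: str = "cost", lam_min_ratio: float = 1e-3,
                   add_squares: Sequence[str] = (), tol: float = 1e-6,
                   max_iter: int = 5000,
                   group_weights: str | dict | None = None) -> CVResult:
    """k-fold CV of the sparse group lasso over an (alpha, lambda) grid.

    ``retain=None`` runs on the raw standardized dummy design (no PCA), the
    comparison condition for the pre-processing contrast.
    ``group_weights="sqrt"`` applies sqrt(group size) weights to the group-norm
    term and ``"concentration"`` the support-recovery weights
    sqrt(p_j) + sqrt(2 log m) (both recomputed per fold from that fold's
    design); ``None`` keeps the unweighted penalty.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(records):
        raise ValueError("k exceeds the number of rows")
    if len(alpha_grid) == 0 or n_lambda < 2:
        raise ValueError("grids must be non-empty (n_lambda >= 2)")
    alpha_grid = np.asarray(sorted(alpha_grid), dtype=float)

    def weights_for(design):
        if group_weights == "sqrt":
            return sgl.sqrt_size_weights(design)
        if group_weights == "concentration":
            return sgl.concentration_weights(design)
        return group_weights

    y_all = records[outcome].to_numpy(dtype=float)
    design_full, _ = fit_design(records, roster, retain=retain, add_squares=add_squares)
    w_full = weights_for(design_full)
    lam_grid = np.empty((len(alpha_grid), n_lambda))
    for i, a in enumerate(alpha_grid):
        lmax = sgl.lambda_max(design_full, y_all, float(a), group_weights=w_full)
        lam_grid[i] = np.geomspace(lmax, lmax * lam_min_ratio, n_lambda)

    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(records))
    err = np.zeros((len(alpha_grid), n_lambda, k))
    for f, (tr, te) in enumerate(folds):
        rec_tr = records.iloc[tr]
        rec_te = records.iloc[te]
        design_tr, ft = fit_design(rec_tr, roster, retain=retain, add_squares=add_squares)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unseen held-out levels map to zeros
            design_te = apply_transform(ft, rec_te)
        y_tr = rec_tr[outcome].to_numpy(dtype=float)
        y_te = rec_te[outcome].to_numpy(dtype=float)
        w_tr = weights_for(design_tr)
        for i, a in enumerate(alpha_grid):
            fits = sgl.fit_path(design_tr, y_tr, float(a), lam_grid[i],
                                tol=tol, max_iter=max_iter, group_weights=w_tr)
            for j, fr in enumerate(fits):
                pred = fr.intercept + design_te.matrix @ fr.beta
                err[i, j, f] = float(np.mean((y_te - pred) ** 2))

    mean_error = err.mean(axis=2)
    se_error = err.std(axis=2, ddof=1) / np.sqrt(k)
    best_i, best_j = _argmin_sparse(mean_error)
    best = (float(alpha_grid[best_i]), float(lam_grid[best_i, best_j]))
    # one-standard-error rule: sparsest (largest-lambda) model within 1 SE of
    # the minimum, searched along the minimizing alpha row
    cutoff = mean_error[best_i, best_j] + se_error[best_i, best_j]
    j_1se = int(np.flatnonzero(mean_error[best_i] <= cutoff)[0])
    best_1se = (float(alpha_grid[best_i]), float(lam_grid[best_i, j_1se]))
    return CVResult(alpha_grid=alpha_grid, lam_grid=lam_grid,
                    mean_error=mean_error, se_error=se_error,
                    best=best, best_index=(best_i, best_j),
                    best_1se=best_1se, best_1se_index=(best_i, j_1se),
                    fold_seed=seed, k=k)


def _argmin_sparse(mean_error: np.ndarray) -> tuple[int, int]:
    """Grid argmin; ties break toward larger lambda (smaller column index),
    then larger alpha (larger row index)."""
    m = mean_error.min()
    ties = np.argwhere(mean_error == m)
    # sort by (lambda column ascending, alpha row descending)
    ties = sorted(map(tuple, ties), key=lambda t: (t[1], -t[0]))
    return int(ties[0][0]), int(ties[0][1])


def error_curve_has_interior_minimum(cv: CVResult, alpha: float) -> bool:
    """True when the minimizing lambda for this alpha slice is strictly inside
    the grid — the qualitative signature of a well-behaved CV curve."""
    _, errs = cv.curve(alpha)
    j = int(np.argmin(errs))  # first (largest-lambda) minimizer on ties
    return 0 < j < len(errs) - 1


def subsample_rows(records: pd.DataFrame, fraction: float, seed: int,
                   repeats: int = 1) -> list[pd.DataFrame]:
    """Seeded random row fractions (without replacement), one per repeat."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    m = max(1, int(round(fraction * n)))
    return [records.iloc[rng.choice(n, size=m, replace=False)] for _ in range(repeats)]
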