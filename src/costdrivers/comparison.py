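"""Unpenalized benchmark arm: OLS on the identical design, VIF, nonlinearity.

The penalized decomposition is paralleled by plain least squares on the same
pre-processed design.  Exactly collinear columns cannot be estimated there:
a rank check flags them, their drivers are reported "not estimated", and the
variance inflation factors quantify the remaining near-collinearity.  The
contrast between the two arms — a penalized fit that stays finite and
certified under exact collinearity versus an OLS fit that must drop columns —
is the core methodological argument of the pipeline.

Rank attribution scans groups in descending column-count order, so when a
small derived flag duplicates information held in a large casemix group it
is the flag, not a casemix component, that is reported as not estimable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import sgl
from .aggregate import AggregateReport, aggregate_coefficients
from .preprocess import GroupedDesign, fit_design
from .roster import PredictorSpec

RANK_RTOL = 1e-10   # singular values below this fraction of the largest are null


@dataclass
class OLSReport:
    coefficients: np.ndarray     # per design column; NaN where not estimable
    estimable: np.ndarray        # boolean per column
    not_estimated: list          # drivers with at least one dropped column
    vif: np.ndarray              # per column; inf where exactly collinear
    mean_vif: float              # mean over finite entries
    aggregate_report: AggregateReport

    def to_frame(self) -> pd.DataFrame:
        df = self.aggregate_report.to_frame()
        df["not_estimated"] = df["driver"].isin(self.not_estimated)
        return df


def _column_precedence(design: GroupedDesign) -> np.ndarray:
    order = sorted(design.groups, key=lambda g: -len(design.groups[g]))
    return np.concatenate([design.groups[g] for g in order if len(design.groups[g])]).astype(int)


def _independent_columns(X: np.ndarray, precedence: np.ndarray) -> np.ndarray:
    """Boolean mask of columns estimable after all preceding (precedence-ordered)
    columns, via incremental Gram-Schmidt with reorthogonalization."""
    n, p = X.shape
    keep = np.zeros(p, dtype=bool)
    Q = np.empty((n, 0))
    ref = max(float(np.linalg.norm(X[:, j])) for j in range(p)) if p else 0.0
    for j in precedence:
        v = X[:, j].astype(float).copy()
        for _ in range(2):
            if Q.shape[1]:
                v -= Q @ (Q.T @ v)
        nv = float(np.linalg.norm(v))
        if nv > RANK_RTOL * ref:
            keep[j] = True
            Q = np.column_stack([Q, v / nv])
    return keep


def fit_ols(design: GroupedDesign, y: np.ndarray,
            roster: Sequence[PredictorSpec]) -> OLSReport:
    """Least squares with rank-revealing collinearity handling.

    Columns lying in the span of higher-precedence columns are flagged not
    estimable and excluded; their drivers appear in ``not_estimated``.
    Aggregates and shares use the identical statistic as the penalized arm
    (dropped columns contribute zero).
    """
    X = design.matrix
    if X.shape[1] == 0:
        raise ValueError("empty design")
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    keep = _independent_columns(X, _column_precedence(design))
    beta = np.full(X.shape[1], np.nan)
    sol, *_ = np.linalg.lstsq(X[:, keep], yc, rcond=None)
    beta[keep] = sol
    not_est = [g for g, idx in design.groups.items()
               if len(idx) and not keep[np.asarray(idx, int)].all()]
    v = vif(design)
    finite = np.isfinite(v)
    report = aggregate_coefficients(beta, design, roster)
    return OLSReport(coefficients=beta, estimable=keep, not_estimated=not_est,
                     vif=v, mean_vif=float(v[finite].mean()) if finite.any() else np.nan,
                     aggregate_report=report)


def vif(design: GroupedDesign) -> np.ndarray:
    """Variance inflation factors, VIF_k = 1 / (1 - R^2_k).

    Requires standardized columns.  Every column participating in an exact
    linear dependence has R^2 = 1 against the others and is flagged infinite;
    the remaining factors come from the inverse correlation matrix restricted
    to a maximal independent column set (which leaves their regressor span
    unchanged).
    """
    X = design.matrix
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if not design.standardized:
        raise ValueError("VIF is defined here on standardized columns")
    C = X.T @ X / n
    evals, evecs = np.linalg.eigh(C)
    null = evals < RANK_RTOL * max(float(evals[-1]), 1.0)
    flagged = np.zeros(p, dtype=bool)
    if null.any():
        load = np.abs(evecs[:, null]).max(axis=1)
        flagged = load > 1e-6
    out = np.full(p, np.inf)
    free = ~flagged
    if free.any():
        sub = C[np.ix_(free, free)]
        inv = np.linalg.inv(sub)
        out[free] = np.diag(inv)
    return out


# ---------------------------------------------------------------------------
# nonlinearity re-run on subsamples


@dataclass
class NonlinearityReport:
    per_target: dict    # target -> {"aggregates": [..], "inside_ci": [..], "verdict": str}
    fraction: float
    repeats: int
    seed: int


def nonlinearity_check(records: pd.DataFrame, roster: Sequence[PredictorSpec],
                       targets: Sequence[str], penalty: sgl.PenaltyConfig,
                       baseline_ci: dict, retain: float | None = 0.995,
                       fraction: float = 0.10, repeats: int = 3, seed: int = 0,
                       outcome: str = "cost", tol: float = 1e-6,
                       max_iter: int = 5000) -> NonlinearityReport:
    """Squared-term sensitivity analysis on repeated random subsamples.

    Each repeat refits the penalized pipeline on a seeded random fraction of
    the rows with squared terms added to the target drivers and reports, per
    target, the combined |linear| + |squared| aggregate and whether it falls
    inside that driver's baseline bootstrap interval.  The verdict is
    "linearity adequate" when the majority of repeats land inside the
    interval, "nonlinearity detected" otherwise; no p-value is computed.
    """
    kinds = {p.name: p.kind for p in roster}
    for t in targets:
        if kinds.get(t) not in ("continuous", "ordinal"):
            raise ValueError(f"nonlinearity target {t!r} must be continuous/ordinal")
        if t not in baseline_ci:
            raise ValueError(f"no baseline confidence interval supplied for {t!r}")

    from .selection import subsample_rows

    subs = subsample_rows(records, fraction, seed, repeats=repeats)
    per_target: dict = {t: {"aggregates": [], "inside_ci": []} for t in targets}
    for rec in subs:
        design, _ = fit_design(rec, roster, retain=retain, add_squares=targets)
        y = rec[outcome].to_numpy(dtype=float)
        fr = sgl.fit(design, y, penalty, tol=tol, max_iter=max_iter,
                     record_objective=False)
        rep = aggregate_coefficients(fr.beta, design, roster)
        for t in targets:
            agg = rep.driver(t).aggregate
            lo, hi = baseline_ci[t]
            per_target[t]["aggregates"].append(agg)
            per_target[t]["inside_ci"].append(bool(lo <= agg <= hi))
    for t in targets:
        inside = per_target[t]["inside_ci"]
        per_target[t]["verdict"] = ("linearity adequate"
                                    if sum(inside) * 2 > len(inside)
                                    else "nonlinearity detected")
    return NonlinearityReport(per_target=per_target, fraction=fraction,
                              repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# juxtaposition of the two arms


def share_path(design: GroupedDesign, y: np.ndarray,
               roster: Sequence[PredictorSpec], alpha: float,
               lam_grid: Sequence[float], tol: float = 1e-6,
               max_iter: int = 5000) -> pd.DataFrame:
    """Per-driver share of total variability along a decreasing lambda path.

    Columns are lambda values; all-zero fits are reported as NaN shares
    (null model).
    """
    fits = sgl.fit_path(design, y, alpha, lam_grid, tol=tol, max_iter=max_iter)
    out = {}
    for lam, fr in zip(lam_grid, fits, strict=True):
        rep = aggregate_coefficients(fr.beta, design, roster)
        out[float(lam)] = {d.name: (np.nan if rep.null_model else d.share)
                           for d in rep.drivers}
    return pd.DataFrame(out)


def side_by_side(lasso_report: AggregateReport, ols_report: OLSReport,
                 path: pd.DataFrame | None = None) -> pd.DataFrame:
    """Driver-by-driver shares under the penalized and unpenalized fits."""
    lasso_names = [d.name for d in lasso_report.drivers]
    ols_names = [d.name for d in ols_report.aggregate_report.drivers]
    if lasso_names != ols_names:
        raise ValueError("the two reports cover different driver rosters")
    df = pd.DataFrame({
        "driver": lasso_names,
        "predictable": [d.predictable for d in lasso_report.drivers],
        "share_lasso_pct": [d.share for d in lasso_report.drivers],
        "share_ols_pct": [d.share for d in ols_report.aggregate_report.drivers],
        "ols_not_estimated": [n in ols_report.not_estimated for n in lasso_names],
    })
    if path is not None:
        for lam in path.columns:
            df[f"share_at_lam_{lam:.6g}"] = df["driver"].map(path[lam]).to_numpy()
    return df
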