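"""Grouped design construction: imputation, dummy encoding, per-group PCA.

The pipeline turns a flat admission table into a numeric design matrix with an
explicit partition of columns into named groups, one group per cost driver:

* missing numeric indices are filled with the training mean, missing flags
  with the training mode (single mean/mode fill, no multiple imputation);
* every categorical driver with L levels becomes L indicator columns (no
  reference level is dropped — centering plus PCA removes the redundancy);
* every multi-column group is replaced by its principal-component scores,
  keeping the smallest leading set of components reaching the requested
  cumulative-variance fraction; singleton groups are centered only;
* all surviving columns are scaled to unit (population) standard deviation.

After this step the columns inside any one group are exactly uncorrelated,
which is the property that later justifies summing absolute coefficients into
a per-driver aggregate.  The fitted transform is a frozen object: applying it
never refits anything, so cross-validation folds can fit their own transforms
without leaking held-out rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .roster import PredictorSpec, validate_roster

_EIG_TOL = 1e-12  # relative variance below which a component is treated as null


@dataclass
class ColumnInfo:
    """Provenance of one design column: which driver, which level/component."""

    predictor: str
    label: str
    scale: float = 1.0


@dataclass
class GroupedDesign:
    matrix: np.ndarray
    groups: dict  # driver name -> np.ndarray of column indices (ordered)
    columns: list  # list[ColumnInfo], parallel to matrix columns
    orthogonalized: bool = False
    standardized: bool = False

    def validate_partition(self) -> None:
        idx = np.concatenate([v for v in self.groups.values() if len(v)]) if self.groups else np.array([], int)
        if len(idx) != self.matrix.shape[1] or (len(idx) and (np.sort(idx) != np.arange(self.matrix.shape[1])).any()):
            raise ValueError("groups do not partition the design columns")

    @property
    def group_names(self) -> list:
        return list(self.groups)

    def group_matrix(self, name: str) -> np.ndarray:
        return self.matrix[:, self.groups[name]]


@dataclass
class GroupTransform:
    """Per-group frozen parameters: centering, loadings, scales."""

    mean_: np.ndarray                 # per encoded column
    components_: np.ndarray | None    # (k, p) loadings; None = no rotation (singletons)
    scales_: np.ndarray               # per surviving column population sd
    kept: int                         # surviving column count (may be 0)
    dropped_zero_variance: bool = False


@dataclass
class FittedTransform:
    roster: list
    imputation: dict            # predictor -> fill value
    levels: dict                # predictor -> resolved level list (binary/categorical)
    add_squares: tuple
    retain: float | None        # None = no PCA rotation (raw-dummy design)
    groups: dict                # predictor -> GroupTransform

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(g: GroupTransform) -> dict:
            return {
                "mean": g.mean_.tolist(),
                "components": None if g.components_ is None else g.components_.tolist(),
                "scales": g.scales_.tolist(),
                "kept": g.kept,
                "dropped_zero_variance": g.dropped_zero_variance,
            }

        payload = {
            "roster": [
                {"name": p.name, "kind": p.kind, "levels": p.levels, "predictable": p.predictable}
                for p in self.roster
            ],
            "imputation": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in self.imputation.items()},
            "levels": {k: list(v) for k, v in self.levels.items()},
            "add_squares": list(self.add_squares),
            "retain": self.retain,
            "groups": {k: enc(v) for k, v in self.groups.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# imputation


def impute(records: pd.DataFrame, roster: Sequence[PredictorSpec],
           values: Mapping | None = None) -> pd.DataFrame:
    """Fill missing driver values with the mean (numeric) or mode (labels).

    When ``values`` is given (a mapping predictor -> fill value from a fitted
    transform) those values are used verbatim; otherwise fills are computed
    from the non-missing entries of ``records`` itself.  Mode ties break
    toward the first level in declared order (or first-seen order when the
    roster declares no levels).
    """
    validate_roster(roster)
    out = records.copy()
    for p in roster:
        col = out[p.name]
        if not col.isna().any():
            continue
        if values is not None and p.name in values:
            fill = values[p.name]
        elif p.kind in ("continuous", "ordinal"):
            if col.isna().all():
                raise ValueError(f"column {p.name!r} entirely missing; cannot impute a mean")
            fill = float(col.mean())
        else:
            counts = col.value_counts(dropna=True)
            if counts.empty:
                raise ValueError(f"column {p.name!r} entirely missing; cannot impute a mode")
            top = counts.max()
            tied = set(counts[counts == top].index)
            order = p.levels if p.levels is not None else list(dict.fromkeys(col.dropna()))
            fill = next(v for v in order if v in tied)
        out[p.name] = col.fillna(fill)
    return out


def imputation_values(records: pd.DataFrame, roster: Sequence[PredictorSpec]) -> dict:
    """Mean/mode fill values computed from ``records`` for every roster driver."""
    vals: dict = {}
    for p in roster:
        col = records[p.name]
        if p.kind in ("continuous", "ordinal"):
            vals[p.name] = float(col.mean())
        else:
            counts = col.value_counts(dropna=True)
            if counts.empty:
                raise ValueError(f"column {p.name!r} entirely missing")
            top = counts.max()
            tied = set(counts[counts == top].index)
            order = p.levels if p.levels is not None else list(dict.fromkeys(col.dropna()))
            vals[p.name] = next(v for v in order if v in tied)
    return vals


# ---------------------------------------------------------------------------
# encoding


def _resolve_levels(records: pd.DataFrame, p: PredictorSpec) -> list:
    if p.levels is not None:
        return list(p.levels)
    return sorted(pd.unique(records[p.name].dropna()))


def encode(records: pd.DataFrame, roster: Sequence[PredictorSpec],
           add_squares: Sequence[str] = (), levels: Mapping | None = None,
           strict: bool = True) -> GroupedDesign:
    """Dummy-encode the admission table into a grouped design matrix.

    Categorical drivers contribute one indicator column per level (a full
    one-hot block, forming one group); binary drivers one indicator of their
    second level; continuous/ordinal drivers their numeric value (the ordinal
    comorbidity index enters as its integer score under the linearity
    assumption).  Drivers named in ``add_squares`` contribute an extra squared
    column inside the same group.

    ``strict=True`` raises on values outside the declared levels; the
    non-strict path (used when applying a frozen transform) maps unseen levels
    to an all-zero indicator block and emits a warning.
    """
    validate_roster(roster)
    add_squares = tuple(add_squares)
    unknown = [s for s in add_squares if s not in {p.name for p in roster}]
    if unknown:
        raise ValueError(f"add_squares names not in roster: {unknown}")
    for s in add_squares:
        spec = next(p for p in roster if p.name == s)
        if spec.kind not in ("continuous", "ordinal"):
            raise ValueError(f"add_squares target {s!r} must be continuous/ordinal")

    n = len(records)
    blocks: list[np.ndarray] = []
    groups: dict = {}
    columns: list[ColumnInfo] = []
    pos = 0
    for p in roster:
        col = records[p.name]
        if col.isna().any():
            raise ValueError(f"column {p.name!r} still has missing values; impute first")
        if p.kind in ("continuous", "ordinal"):
            x = col.to_numpy(dtype=float)
            block = x[:, None]
            labels = ["linear"]
            if p.name in add_squares:
                block = np.column_stack([x, x * x])
                labels = ["linear", "squared"]
        elif p.kind == "binary":
            lv = _resolve_levels(records, p) if levels is None else list(levels[p.name])
            codes = pd.Categorical(col, categories=lv).codes
            if strict and (codes < 0).any():
                bad = sorted(set(col[codes < 0]))
                raise ValueError(f"column {p.name!r} has values outside declared levels: {bad}")
            if not strict and (codes < 0).any():
                warnings.warn(f"column {p.name!r}: unseen levels mapped to zero indicators")
            block = (codes == 1).astype(float)[:, None]
            labels = [str(lv[1])]
        else:  # categorical
            lv = _resolve_levels(records, p) if levels is None else list(levels[p.name])
            codes = pd.Categorical(col, categories=lv).codes
            if strict and (codes < 0).any():
                bad = sorted(set(col[codes < 0]))
                raise ValueError(f"column {p.name!r} has values outside declared levels: {bad}")
            if not strict and (codes < 0).any():
                warnings.warn(f"column {p.name!r}: unseen levels mapped to zero indicators")
            block = np.zeros((n, len(lv)))
            seen = codes >= 0
            block[np.arange(n)[seen], codes[seen]] = 1.0
            labels = [str(v) for v in lv]
        blocks.append(block)
        groups[p.name] = np.arange(pos, pos + block.shape[1])
        columns.extend(ColumnInfo(p.name, lab) for lab in labels)
        pos += block.shape[1]

    design = GroupedDesign(np.hstack(blocks) if blocks else np.empty((n, 0)),
                           groups, columns)
    design.validate_partition()
    return design


def resolved_levels(records: pd.DataFrame, roster: Sequence[PredictorSpec]) -> dict:
    return {p.name: _resolve_levels(records, p)
            for p in roster if p.kind in ("binary", "categorical")}


# ---------------------------------------------------------------------------
# orthogonalization


def orthogonalize(design: GroupedDesign, retain: float = 0.995,
                  transform: FittedTransform | None = None
                  ) -> tuple[GroupedDesign, FittedTransform]:
    """Replace every multi-column group by standardized principal-component scores.

    ``retain`` is the per-group cumulative explained-variance fraction; the
    smallest leading component set reaching it survives (``retain=1.0`` keeps
    every positive-variance component).  Singleton groups are centered and
    standardized without rotation.  Zero-variance columns/components are
    dropped and recorded on the returned transform.  The component sign
    convention (largest-magnitude loading entry positive, sklearn's svd_flip)
    makes the output deterministic.
    """
    if transform is None and not (0.0 < retain <= 1.0):
        raise ValueError(f"retain must be in (0, 1], got {retain}")

    X = design.matrix
    n = X.shape[0]
    out_blocks: list[np.ndarray] = []
    out_groups: dict = {}
    out_cols: list[ColumnInfo] = []
    gts: dict = {}
    pos = 0
    for name, idx in design.groups.items():
        B = X[:, idx]
        if transform is not None:
            gt = transform.groups[name]
            gts[name] = gt
            Bc = B - gt.mean_
            scores = Bc if gt.components_ is None else Bc @ gt.components_.T
            if gt.kept == 0:
                out_groups[name] = np.arange(pos, pos)
                gts[name] = gt
                continue
            Z = scores[:, : gt.kept] / gt.scales_
        else:
            mean = B.mean(axis=0)
            Bc = B - mean
            if B.shape[1] == 1:
                sd = float(Bc.std(ddof=0))
                if sd <= 0.0:
                    gt = GroupTransform(mean, None, np.empty(0), 0, dropped_zero_variance=True)
                    gts[name] = gt
                    out_groups[name] = np.arange(pos, pos)
                    continue
                gt = GroupTransform(mean, None, np.array([sd]), 1)
                Z = Bc / sd
            else:
                total_var = Bc.var(axis=0, ddof=0).sum()
                if total_var <= 0.0:
                    gt = GroupTransform(mean, None, np.empty(0), 0, dropped_zero_variance=True)
                    gts[name] = gt
                    out_groups[name] = np.arange(pos, pos)
                    continue
                pca = PCA(n_components=None, svd_solver="full")
                scores = pca.fit_transform(B)
                evr = pca.explained_variance_ratio_
                positive = evr > _EIG_TOL
                if retain >= 1.0:
                    kept = int(positive.sum())
                else:
                    kept = int(np.searchsorted(np.cumsum(evr), retain) + 1)
                    kept = min(kept, int(positive.sum()))
                kept = max(kept, 1)
                sds = scores[:, :kept].std(axis=0, ddof=0)
                good = sds > 0
                comp = pca.components_[:kept][good]
                sds = sds[good]
                kept = int(good.sum())
                gt = GroupTransform(pca.mean_, comp, sds, kept,
                                    dropped_zero_variance=not positive.all())
                Z = scores[:, : len(good)][:, good] / sds
            gts[name] = gt

        k = Z.shape[1]
        out_blocks.append(Z)
        out_groups[name] = np.arange(pos, pos + k)
        if gts[name].components_ is None:
            base = design.columns[idx[0]]
            out_cols.append(ColumnInfo(name, base.label, float(gts[name].scales_[0])))
        else:
            out_cols.extend(ColumnInfo(name, f"pc{j + 1}", float(gts[name].scales_[j])) for j in range(k))
        pos += k

    ortho = GroupedDesign(np.hstack(out_blocks) if out_blocks else np.empty((n, 0)),
                          out_groups, out_cols, orthogonalized=True, standardized=True)
    ortho.validate_partition()
    if transform is not None:
        return ortho, transform
    ft = FittedTransform(roster=[], imputation={}, levels={}, add_squares=(),
                         retain=retain, groups=gts)
    return ortho, ft


# ---------------------------------------------------------------------------
# end-to-end fitting and application


def fit_design(records: pd.DataFrame, roster: Sequence[PredictorSpec],
               retain: float | None = 0.995, add_squares: Sequence[str] = ()
               ) -> tuple[GroupedDesign, FittedTransform]:
    """Impute, encode and (optionally) orthogonalize, returning a frozen transform.

    ``retain=None`` skips the PCA rotation and returns the centered,
    standardized raw-dummy design (the un-pre-processed comparison arm);
    zero-variance columns are still dropped.
    """
    validate_roster(roster)
    imp = imputation_values(records, roster)
    filled = impute(records, roster, values=imp)
    lv = resolved_levels(filled, roster)
    design = encode(filled, roster, add_squares=add_squares, levels=lv)
    if retain is None:
        ortho, ft = _standardize_raw(design)
    else:
        ortho, ft = orthogonalize(design, retain=retain)
    ft.roster = list(roster)
    ft.imputation = imp
    ft.levels = lv
    ft.add_squares = tuple(add_squares)
    return ortho, ft


def _standardize_raw(design: GroupedDesign) -> tuple[GroupedDesign, FittedTransform]:
    # center + unit-sd scale every column, drop zero variance, no rotation
    X = design.matrix
    gts: dict = {}
    blocks, groups, cols = [], {}, []
    pos = 0
    for name, idx in design.groups.items():
        B = X[:, idx]
        mean = B.mean(axis=0)
        Bc = B - mean
        sd = Bc.std(axis=0, ddof=0)
        good = sd > 0
        kept = int(good.sum())
        comp = np.eye(B.shape[1])[good] if B.shape[1] > 1 else None
        if B.shape[1] > 1:
            gt = GroupTransform(mean, comp, sd[good], kept, dropped_zero_variance=not good.all())
        else:
            gt = GroupTransform(mean, None, sd[good], kept, dropped_zero_variance=not good.all())
        gts[name] = gt
        if kept:
            blocks.append(Bc[:, good] / sd[good])
            groups[name] = np.arange(pos, pos + kept)
            kept_idx = np.flatnonzero(good)
            cols.extend(ColumnInfo(name, design.columns[idx[j]].label, float(sd[j])) for j in kept_idx)
            pos += kept
        else:
            groups[name] = np.arange(pos, pos)
    out = GroupedDesign(np.hstack(blocks) if blocks else np.empty((X.shape[0], 0)),
                        groups, cols, orthogonalized=False, standardized=True)
    out.validate_partition()
    ft = FittedTransform(roster=[], imputation={}, levels={}, add_squares=(),
                         retain=None, groups=gts)
    return out, ft


def apply_transform(transform: FittedTransform, records: pd.DataFrame) -> GroupedDesign:
    """Project new admission rows through a frozen transform (never refits).

    Missing values are filled with the stored training means/modes; unseen
    categorical levels map to an all-zero indicator block with a warning.
    """
    filled = impute(records, transform.roster, values=transform.imputation)
    design = encode(filled, transform.roster, add_squares=transform.add_squares,
                    levels=transform.levels, strict=False)
    X = design.matrix
    blocks, groups, cols = [], {}, []
    pos = 0
    for name, idx in design.groups.items():
        gt = transform.groups[name]
        if gt.kept == 0:
            groups[name] = np.arange(pos, pos)
            continue
        Bc = X[:, idx] - gt.mean_
        scores = Bc if gt.components_ is None else Bc @ gt.components_.T
        Z = scores[:, : gt.kept] / gt.scales_
        blocks.append(Z)
        groups[name] = np.arange(pos, pos + gt.kept)
        if gt.components_ is None:
            cols.append(ColumnInfo(name, design.columns[idx[0]].label, float(gt.scales_[0])))
        else:
            cols.extend(ColumnInfo(name, f"pc{j + 1}", float(gt.scales_[j])) for j in range(gt.kept))
        pos += gt.kept
    out = GroupedDesign(np.hstack(blocks) if blocks else np.empty((len(records), 0)),
                        groups, cols,
                        orthogonalized=transform.retain is not None, standardized=True)
    out.validate_partition()
    return out


def max_within_group_correlation(design: GroupedDesign) -> float:
    """Largest absolute off-diagonal sample correlation inside any group."""
    worst = 0.0
    for idx in design.groups.values():
        if len(idx) < 2:
            continue
        B = design.matrix[:, idx]
        C = np.corrcoef(B, rowvar=False)
        off = np.abs(C - np.diag(np.diag(C))).max()
        worst = max(worst, float(off))
    return worst
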