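"""Synthetic admission-record generator with known ground truth.

Emulates the statistical structure of a single-hospital admission extract:
a high-cardinality casemix group (a DRG analog with hundreds of levels,
zipf-like level frequencies), attending-doctor analogs with ~100 levels,
ward/unit groups with 15–25 levels, calendar fields (day of week, month,
hour) carrying no true effect, continuous socio-economic indices and age, an
ordinal comorbidity score, right-skewed strictly positive costs, sparse
missingness in the numeric indices plus isolated missing flags, and binary
flags that are exact deterministic functions of the casemix level (the
source of exact collinearity in the unpenalized arm).

Costs follow a multiplicative model: cost = exp(b0 + eta + noise) where eta
sums per-driver effects (per-level draws for categoricals, fixed indicator
coefficients for binaries, z-scored linear terms for continuous/ordinal
drivers), with log-normal noise by default or a gamma alternative with mean
exp(b0 + eta).  The generator returns the full ground truth needed for
recovery tests, including an oracle decomposition of the noiseless cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import AggregateReport, aggregate_coefficients
from .preprocess import fit_design
from .roster import PredictorSpec, validate_roster


@dataclass
class CostNoise:
    family: str = "lognormal"      # lognormal | gamma
    dispersion: float = 0.4        # sd of log-noise / gamma CV

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class Missingness:
    numeric_rate: float = 326.0 / 53224.0   # fraction of rows losing the indices
    flag_missing_count: int = 1             # isolated missing flag cells
    numeric_targets: tuple = ("irsad", "irsd")

    def __post_init__(self) -> None:
        if not 0.0 <= self.numeric_rate <= 1.0:
            raise ValueError("numeric_rate must lie in [0, 1]")
        if self.flag_missing_count < 0:
            raise ValueError("flag_missing_count must be nonnegative")


@dataclass
class CollinearPair:
    source: str     # categorical driver
    derived: str    # binary driver defined as 1{source level in subset}
    fraction: float = 0.25


@dataclass
class GeneratorConfig:
    n_records: int
    roster: list
    effect_scales: dict                  # driver -> scale of its true effect
    signal_groups: list
    null_groups: list
    cost_noise: CostNoise = field(default_factory=CostNoise)
    collinear_pairs: list = field(default_factory=list)
    missingness: Missingness = field(default_factory=Missingness)
    seed: int = 0
    baseline_log_cost: float = 8.3       # exp(8.3) ~ $4,000 typical admission
    continuous_params: dict = field(default_factory=dict)   # name -> (mean, sd)
    continuous_corr: list = field(default_factory=list)     # (a, b, rho) on z-scale
    ordinal_params: dict = field(default_factory=dict)      # name -> (n_max, p)
    binary_rates: dict = field(default_factory=dict)        # name -> P(flag = 1)

    def __post_init__(self) -> None:
        validate_roster(self.roster)
        names = {p.name for p in self.roster}
        for bag, label in ((self.signal_groups, "signal_groups"),
                           (self.null_groups, "null_groups"),
                           (self.effect_scales, "effect_scales")):
            unknown = [x for x in bag if x not in names]
            if unknown:
                raise ValueError(f"{label} reference unknown predictors: {unknown}")
        overlap = set(self.signal_groups) & set(self.null_groups)
        if overlap:
            raise ValueError(f"signal and null groups overlap: {sorted(overlap)}")
        uncovered = names - set(self.signal_groups) - set(self.null_groups)
        if uncovered:
            raise ValueError(f"roster drivers in neither signal nor null set: {sorted(uncovered)}")
        for cp in self.collinear_pairs:
            if cp.source not in names or cp.derived not in names:
                raise ValueError(f"collinear pair ({cp.source}, {cp.derived}) references unknown predictors")
        for p in self.roster:
            if p.kind == "categorical" and p.levels is not None and len(p.levels) < 2:
                raise ValueError(f"categorical {p.name!r} needs >= 2 levels")

    def spec(self, name: str) -> PredictorSpec:
        return next(p for p in self.roster if p.name == name)


@dataclass
class SyntheticTruth:
    baseline_log_cost: float
    effects: dict                 # driver -> effect description (see generate)
    signal_groups: list
    null_groups: list
    noise: CostNoise
    collinear_subsets: dict       # derived -> sorted source levels mapping to 1

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Recompute eta (log-scale signal, baseline excluded) for any rows."""
        eta = np.zeros(len(records))
        for name, eff in self.effects.items():
            kind = eff["kind"]
            if kind == "categorical":
                lut = eff["levels"]
                eta += records[name].map(lut).to_numpy(dtype=float)
            elif kind == "binary":
                ind = (records[name] == eff["one_level"]).to_numpy(dtype=float)
                eta += eff["coef"] * ind
            else:
                z = (records[name].to_numpy(dtype=float) - eff["center"]) / eff["scale"]
                eta += eff["coef"] * z
        return eta

    def noiseless_cost(self, records: pd.DataFrame) -> np.ndarray:
        return np.exp(self.baseline_log_cost + self.linear_predictor(records))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline_log_cost": self.baseline_log_cost,
            "signal_groups": list(self.signal_groups),
            "null_groups": list(self.null_groups),
            "noise": {"family": self.noise.family, "dispersion": self.noise.dispersion},
            "collinear_subsets": {k: list(v) for k, v in self.collinear_subsets.items()},
            "effects": self.effects,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    truth: SyntheticTruth
    config: GeneratorConfig

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "admissions.csv", index=False)
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig, data_seed: int | None = None) -> SyntheticDataset:
    """Draw an admission table plus ground truth from the configured model.

    The ground truth (per-level effects, collinear level subsets) is a
    deterministic function of ``config.seed`` alone; the admission rows and
    noise come from ``data_seed`` (defaulting to ``config.seed``), so
    repeated draws with different ``data_seed`` values share one fixed truth
    — the setup replication studies need.
    """
    if config.n_records <= 0:
        raise ValueError("n_records must be positive")
    rng_truth = np.random.default_rng([config.seed, 17])
    rng = np.random.default_rng([config.seed if data_seed is None else data_seed, 29])
    n = config.n_records
    derived_names = {cp.derived for cp in config.collinear_pairs}
    scale_of = {p.name: float(config.effect_scales.get(p.name, 0.0)) for p in config.roster}
    for g in config.null_groups:
        scale_of[g] = 0.0

    cols: dict = {}
    effects: dict = {}
    z_latent: dict = {}   # continuous z-scores before affine mapping

    # continuous drivers first so declared correlations can be wired on z-scale
    cont = [p for p in config.roster if p.kind == "continuous"]
    for p in cont:
        z_latent[p.name] = rng.standard_normal(n)
    for a, b, rho in config.continuous_corr:
        z_latent[b] = rho * z_latent[a] + np.sqrt(1.0 - rho**2) * z_latent[b]

    for p in config.roster:
        s = scale_of[p.name]
        if p.kind == "continuous":
            mean, sd = config.continuous_params.get(p.name, (0.0, 1.0))
            x = mean + sd * z_latent[p.name]
            cols[p.name] = x
            effects[p.name] = {"kind": "continuous", "coef": s, "center": mean, "scale": sd}
        elif p.kind == "ordinal":
            n_max, pr = config.ordinal_params.get(p.name, (10, 0.15))
            x = rng.binomial(n_max, pr, size=n)
            cols[p.name] = x
            effects[p.name] = {"kind": "ordinal", "coef": s,
                               "center": n_max * pr,
                               "scale": float(np.sqrt(n_max * pr * (1 - pr)))}
        elif p.kind == "binary":
            if p.name in derived_names:
                continue  # filled after categorical sources exist
            lv = p.levels if p.levels is not None else [0, 1]
            pr = config.binary_rates.get(p.name, 0.3)
            ind = rng.random(n) < pr
            cols[p.name] = np.where(ind, lv[1], lv[0])
            effects[p.name] = {"kind": "binary", "coef": s, "one_level": lv[1]}
        else:  # categorical
            lv = p.levels
            if lv is None:
                raise ValueError(f"categorical {p.name!r} must declare levels for generation")
            L = len(lv)
            w = (np.arange(L) + 1.0) ** -0.8   # zipf-like casemix frequencies
            pvec = w / w.sum()
            codes = rng.choice(L, size=n, p=pvec)
            cols[p.name] = np.asarray(lv, dtype=object)[codes]
            per_level = rng_truth.normal(0.0, s, size=L) if s > 0 else np.zeros(L)
            effects[p.name] = {"kind": "categorical",
                               "levels": {str(lv[i]): float(per_level[i]) for i in range(L)}}

    collinear_subsets: dict = {}
    for cp in config.collinear_pairs:
        src = config.spec(cp.source)
        dv = config.spec(cp.derived)
        lv = dv.levels if dv.levels is not None else [0, 1]
        L = len(src.levels)
        subset = np.sort(rng_truth.choice(L, size=max(1, int(round(cp.fraction * L))), replace=False))
        chosen = {str(src.levels[i]) for i in subset}
        ind = pd.Series(cols[cp.source]).astype(str).isin(chosen).to_numpy()
        cols[cp.derived] = np.where(ind, lv[1], lv[0])
        effects[cp.derived] = {"kind": "binary", "coef": scale_of[cp.derived], "one_level": lv[1]}
        collinear_subsets[cp.derived] = sorted(chosen)

    records = pd.DataFrame({p.name: cols[p.name] for p in config.roster})
    truth = SyntheticTruth(
        baseline_log_cost=config.baseline_log_cost,
        effects=effects,
        signal_groups=list(config.signal_groups),
        null_groups=list(config.null_groups),
        noise=config.cost_noise,
        collinear_subsets=collinear_subsets,
    )
    eta = truth.linear_predictor(records)
    mu = config.baseline_log_cost + eta
    if config.cost_noise.family == "lognormal":
        cost = np.exp(mu + rng.normal(0.0, config.cost_noise.dispersion, size=n))
    else:
        shape = 1.0 / config.cost_noise.dispersion ** 2
        cost = rng.gamma(shape, np.exp(mu) / shape, size=n)
        cost = np.maximum(cost, np.finfo(float).tiny)
    records["cost"] = cost

    # sparse missingness: indices vanish together (a missing-postcode analog),
    # plus isolated missing flag cells
    miss = config.missingness
    targets = [t for t in miss.numeric_targets if t in records.columns]
    n_miss = int(round(miss.numeric_rate * n))
    if targets and n_miss:
        rows = rng.choice(n, size=n_miss, replace=False)
        for t in targets:
            records[t] = records[t].astype(float)
            records.loc[rows, t] = np.nan
    # derived flags are exact functions of the casemix coding, so isolated
    # missingness is injected only into the independently sampled flags
    flag_cols = [p.name for p in config.roster
                 if p.kind == "binary" and p.name not in derived_names]
    for _ in range(miss.flag_missing_count):
        if not flag_cols:
            break
        c = flag_cols[int(rng.integers(len(flag_cols)))]
        records[c] = records[c].astype(float) if records[c].dtype.kind in "iub" else records[c]
        records.loc[int(rng.integers(n)), c] = np.nan

    return SyntheticDataset(records=records, truth=truth, config=config)


def oracle_report(dataset: SyntheticDataset, retain: float | None = 0.995,
                  add_squares: Sequence[str] = ()) -> AggregateReport:
    """Ground-truth share decomposition of the noiseless cost.

    Projects exp(b0 + eta) onto the same orthogonalized standardized design
    the pipeline fits (minimum-norm least squares, exact collinearity
    tolerated) and aggregates with the shared statistic.  The resulting
    shares are the population target of the penalized pipeline because the
    noise is a positive multiplicative factor with constant mean.
    """
    from .preprocess import impute, imputation_values

    roster = dataset.config.roster
    filled = impute(dataset.records, roster,
                    values=imputation_values(dataset.records, roster))
    design, _ = fit_design(filled, roster, retain=retain, add_squares=add_squares)
    y0 = dataset.truth.noiseless_cost(filled)
    yc = y0 - y0.mean()
    beta, *_ = np.linalg.lstsq(design.matrix, yc, rcond=None)
    return aggregate_coefficients(beta, design, roster)


# ---------------------------------------------------------------------------
# the published-roster configuration


def default_paper_roster(n_records: int = 53224, seed: int = 0,
                         dispersion: float = 0.4) -> GeneratorConfig:
    """Generator configuration mirroring the 24-driver published roster.

    Level counts: casemix (DRG analog) 617; doctor analogs 100 each; units
    and wards 20/20/25/15; calendar fields 7/12/24; a 3-level veteran-status
    group; binary flags; age and two socio-economic indices as continuous
    terms and an 11-level ordinal comorbidity score.  Calendar and doctor
    groups carry no true effect; casemix, age, the indices and the ward/unit
    groups carry the dominant effects, with small effects on the clinical
    flags.  The alcohol and obesity flags are exact functions of the casemix
    level, reproducing the exact-collinearity failure of the unpenalized arm.
    """

    def cat(name, L, predictable, prefix):
        return PredictorSpec(name, "categorical",
                             [f"{prefix}{i:03d}" for i in range(L)], predictable)

    roster = [
        PredictorSpec("age", "continuous", None, True),
        PredictorSpec("alcohol_overuse", "binary", [0, 1], True),
        PredictorSpec("charlson_index", "ordinal", None, True),
        PredictorSpec("discharge_last_3d", "binary", [0, 1], True),
        PredictorSpec("discharge_last_7d", "binary", [0, 1], True),
        PredictorSpec("discharge_last_14d", "binary", [0, 1], True),
        PredictorSpec("discharge_last_21d", "binary", [0, 1], True),
        cat("drg", 617, True, "DRG"),
        cat("dva_status", 3, True, "DVA"),
        PredictorSpec("irsad", "continuous", None, True),
        PredictorSpec("irsd", "continuous", None, True),
        PredictorSpec("obesity", "binary", [0, 1], True),
        PredictorSpec("private_insurance", "binary", [0, 1], True),
        PredictorSpec("sex", "binary", [0, 1], True),
        PredictorSpec("smoking", "binary", [0, 1], True),
        cat("admitting_unit", 20, False, "AU"),
        cat("admitting_ward", 20, False, "AW"),
        cat("day_of_week", 7, False, "DOW"),
        cat("discharging_unit", 25, False, "DU"),
        cat("discharge_ward", 15, False, "DW"),
        cat("doctor_admission", 100, False, "DRA"),
        cat("doctor_discharge", 100, False, "DRD"),
        cat("month", 12, False, "M"),
        cat("hour", 24, False, "H"),
    ]
    null_groups = ["day_of_week", "month", "hour", "doctor_admission", "doctor_discharge"]
    signal_groups = [p.name for p in roster if p.name not in null_groups]
    effect_scales = {
        "drg": 0.35, "age": 0.30, "irsad": 0.22, "irsd": 0.20,
        "discharge_ward": 0.30, "discharging_unit": 0.25,
        "admitting_ward": 0.15, "admitting_unit": 0.12,
        "charlson_index": 0.08, "dva_status": 0.03,
        "alcohol_overuse": 0.04, "obesity": 0.04, "smoking": 0.04,
        "private_insurance": 0.02, "sex": 0.02,
        "discharge_last_3d": 0.01, "discharge_last_7d": 0.01,
        "discharge_last_14d": 0.01, "discharge_last_21d": 0.01,
    }
    return GeneratorConfig(
        n_records=n_records,
        roster=roster,
        effect_scales=effect_scales,
        signal_groups=signal_groups,
        null_groups=null_groups,
        cost_noise=CostNoise("lognormal", dispersion),
        collinear_pairs=[CollinearPair("drg", "alcohol_overuse", 0.25),
                         CollinearPair("drg", "obesity", 0.20)],
        missingness=Missingness(),
        seed=seed,
        continuous_params={"age": (53.0, 24.0), "irsad": (1000.0, 80.0),
                           "irsd": (985.0, 85.0)},
        continuous_corr=[("irsad", "irsd", 0.85)],
        ordinal_params={"charlson_index": (10, 0.15)},
        binary_rates={"discharge_last_3d": 0.04, "discharge_last_7d": 0.06,
                      "discharge_last_14d": 0.08, "discharge_last_21d": 0.10,
                      "private_insurance": 0.45, "sex": 0.5, "smoking": 0.18},
    )
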