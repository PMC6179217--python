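import numpy as np
import pytest

from costdrivers import synthetic
from costdrivers.preprocess import ColumnInfo, GroupedDesign
from costdrivers.roster import PredictorSpec


def small_roster():
    """A four-driver roster: one signal categorical, one null categorical,
    one continuous, one binary."""
    return [
        PredictorSpec("procedure", "categorical", [f"P{i}" for i in range(6)], True),
        PredictorSpec("weekday", "categorical", [f"W{i}" for i in range(5)], False),
        PredictorSpec("age", "continuous", None, True),
        PredictorSpec("flag", "binary", [0, 1], True),
    ]


def small_config(n, seed=7, dispersion=0.25, procedure_scale=0.4, **kw):
    defaults = dict(
        n_records=n,
        roster=small_roster(),
        effect_scales={"procedure": procedure_scale, "age": 0.3, "flag": 0.15},
        signal_groups=["procedure", "age", "flag"],
        null_groups=["weekday"],
        cost_noise=synthetic.CostNoise("lognormal", dispersion),
        missingness=synthetic.Missingness(0.0, 0, ()),
        seed=seed,
        continuous_params={"age": (50.0, 20.0)},
    )
    defaults.update(kw)
    return synthetic.GeneratorConfig(**defaults)


def design_from_matrix(X, group_sizes, names=None, orthogonalized=False,
                       standardized=False):
    """Wrap a raw matrix and contiguous group sizes into a GroupedDesign."""
    X = np.asarray(X, dtype=float)
    names = names or [f"g{i}" for i in range(len(group_sizes))]
    groups, cols, pos = {}, [], 0
    for name, size in zip(names, group_sizes, strict=True):
        groups[name] = np.arange(pos, pos + size)
        cols.extend(ColumnInfo(name, f"c{j}") for j in range(size))
        pos += size
    assert pos == X.shape[1]
    d = GroupedDesign(X, groups, cols, orthogonalized=orthogonalized,
                      standardized=standardized)
    d.validate_partition()
    return d


def random_grouped_instance(rng, n_rows=40, max_groups=4, min_groups=2,
                            max_cols=8):
    """A random small regression instance with grouped columns."""
    m = int(rng.integers(min_groups, max_groups + 1))
    sizes = []
    remaining = max_cols - m
    for _ in range(m):
        extra = int(rng.integers(0, remaining + 1)) if remaining > 0 else 0
        sizes.append(1 + extra)
        remaining -= extra
    X = rng.standard_normal((n_rows, sum(sizes)))
    X -= X.mean(axis=0)
    X /= X.std(axis=0, ddof=0)
    beta = rng.standard_normal(sum(sizes)) * (rng.random(sum(sizes)) < 0.6)
    y = X @ beta + 0.5 * rng.standard_normal(n_rows)
    return design_from_matrix(X, sizes, standardized=True), y


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
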