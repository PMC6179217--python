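"""Predictor roster: declarations of cost drivers and their measurement kinds.

A roster is an ordered list of :class:`PredictorSpec`, one per cost driver
(admission-level predictor). Each driver is declared as continuous, ordinal,
binary or categorical, and flagged as predictable a-priori (known before the
admission starts, e.g. age or casemix group) or non-predictable (an artefact of
the care process, e.g. discharging ward). The predictable flag is what the
aggregation stage uses to split total cost variability into warranted and
potentially unwarranted subtotals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

KINDS = ("continuous", "ordinal", "binary", "categorical")


@dataclass
class PredictorSpec:
    """One declared cost driver.

    Parameters
    ----------
    name:
        Column name in the admission table; unique within a roster.
    kind:
        ``continuous``, ``ordinal``, ``binary`` or ``categorical``.
    levels:
        Category labels, in declared order, for binary/categorical drivers.
        ``None`` means "infer from the training data" (sorted unique values).
        Continuous/ordinal drivers must not declare levels.
    predictable:
        True when the driver is knowable before the admission starts.
    """

    name: str
    kind: str
    levels: list | None = None
    predictable: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r} for {self.name!r}")
        if self.kind in ("continuous", "ordinal"):
            if self.levels is not None:
                raise ValueError(f"{self.name!r}: {self.kind} drivers carry no levels")
        elif self.levels is not None:
            if self.kind == "categorical" and len(self.levels) < 2:
                raise ValueError(f"{self.name!r}: categorical drivers need >= 2 levels")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"{self.name!r}: binary drivers need exactly 2 levels")

    @property
    def n_levels(self) -> int | None:
        return None if self.levels is None else len(self.levels)


def validate_roster(roster: Sequence[PredictorSpec]) -> None:
    names = [p.name for p in roster]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate predictor names in roster: {dupes}")


def roster_to_records(roster: Iterable[PredictorSpec]) -> list[dict]:
    out = []
    for p in roster:
        d = {"name": p.name, "kind": p.kind, "predictable": p.predictable}
        if p.levels is not None:
            d["levels"] = list(p.levels)
        out.append(d)
    return out


def roster_from_records(records: Iterable[dict]) -> list[PredictorSpec]:
    roster = [
        PredictorSpec(
            name=d["name"],
            kind=d["kind"],
            levels=d.get("levels"),
            predictable=bool(d.get("predictable", True)),
        )
        for d in records
    ]
    validate_roster(roster)
    return roster


def save_roster(roster: Sequence[PredictorSpec], path: str | Path) -> None:
    path = Path(path)
    payload = roster_to_records(roster)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def load_roster(path: str | Path) -> list[PredictorSpec]:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return roster_from_records(payload)
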