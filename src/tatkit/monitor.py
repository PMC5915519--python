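"""Longitudinal therapy monitoring: tumor volume, weight change, endpoints, MTD.

Xenograft studies track each animal's tumor by caliper (volume =
length × width² / 2, with length the longer axis) and its body weight as the
tolerability readout.  Efficacy is summarised per group as the relative
tumor volume (percent of the day-0 value, averaged across animals — mean of
ratios, not ratio of means).  Endpoint rules turn trajectories into survival
events: for analysis, tumor volume reaching 500 mm³ or body-weight loss
exceeding 20 % of baseline; for husbandry, 800 mm³.  The maximum tolerated
dose is the highest administered activity at which no animal exceeds the
weight-loss limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .survstats import EndpointEvent

__all__ = [
    "Observation",
    "Fate",
    "AnimalRecord",
    "EndpointRules",
    "tumor_volume",
    "relative_series",
    "percent_change",
    "group_summary",
    "apply_endpoints",
    "determine_mtd",
    "read_animal_records",
    "write_animal_records",
]

Quantity = Literal["tumor-volume", "body-weight"]


class Observation(NamedTuple):
    day: float
    length_mm: float
    width_mm: float
    body_weight_g: float


@dataclass(frozen=True)
class Fate:
    status: str = "ongoing"  # "ongoing" | "euthanized" | "study-end"
    day: float | None = None
    reason: str = ""


@dataclass
class AnimalRecord:
    """One animal's group assignment and longitudinal measurements."""

    animal_id: str
    group_activity_mbq: float
    observations: list[Observation]
    fate: Fate = field(default_factory=Fate)

    def __post_init__(self) -> None:
        self.observations = [Observation(*o) for o in self.observations]
        days = [o.day for o in self.observations]
        if not days:
            raise ValueError(f"{self.animal_id}: no observations")
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.animal_id}: observation days must be non-decreasing")
        if days[0] != 0:
            raise ValueError(f"{self.animal_id}: a day-0 baseline observation is required")
        for o in self.observations:
            if min(o.length_mm, o.width_mm, o.body_weight_g) < 0:
                raise ValueError(f"{self.animal_id}: negative measurement on day {o.day}")
        if self.group_activity_mbq < 0:
            raise ValueError(f"{self.animal_id}: negative administered activity")

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations], dtype=float)

    def volumes(self) -> np.ndarray:
        return np.array(
            [tumor_volume(o.length_mm, o.width_mm) for o in self.observations]
        )

    def weights(self) -> np.ndarray:
        return np.array([o.body_weight_g for o in self.observations], dtype=float)


@dataclass(frozen=True)
class EndpointRules:
    """Thresholds that trigger endpoint events.

    The weight-loss comparison is strict (loss must exceed the limit: a loss
    of exactly 20 % does not fire); the volume comparisons are inclusive at
    the printed bound for determinism.
    """

    weight_loss_limit: float = 0.20
    humane_volume_mm3: float = 800.0
    analysis_volume_mm3: float = 500.0
    study_end_day: float = 56.0

    def __post_init__(self) -> None:
        if min(self.weight_loss_limit, self.humane_volume_mm3,
               self.analysis_volume_mm3, self.study_end_day) <= 0:
            raise ValueError("all endpoint thresholds must be positive")
        if self.analysis_volume_mm3 > self.humane_volume_mm3:
            raise ValueError("analysis volume endpoint cannot exceed the humane limit")


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm³: length × width² / 2.

    The axes are canonicalised so that length = max(axes); the result is
    therefore symmetric in the argument order.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be non-negative")
    long_ax = max(length_mm, width_mm)
    short_ax = min(length_mm, width_mm)
    return long_ax * short_ax**2 / 2.0


def _series(record: AnimalRecord, quantity: Quantity) -> np.ndarray:
    if quantity == "tumor-volume":
        return record.volumes()
    if quantity == "body-weight":
        return record.weights()
    raise ValueError(f"unknown quantity {quantity!r}")


def relative_series(
    record: AnimalRecord, quantity: Quantity = "tumor-volume"
) -> list[tuple[float, float]]:
    """Per-day values as percent of the day-0 baseline (day 0 → 100 %)."""
    values = _series(record, quantity)
    baseline = values[0]
    if baseline <= 0:
        raise ValueError(f"{record.animal_id}: zero day-0 baseline for {quantity}")
    return [(float(d), 100.0 * v / baseline) for d, v in zip(record.days, values)]


def percent_change(relative_percent: float) -> float:
    """Signed percent change from baseline given a relative value.

    A relative volume of 9.6 % is a decrease of 90.4 %; 509.2 % is an
    increase of 409.2 %.  Negative return values indicate shrinkage.
    """
    if relative_percent < 0:
        raise ValueError("relative percent must be >= 0")
    return relative_percent - 100.0


def _relative_at_day(record: AnimalRecord, day: float, quantity: Quantity) -> float:
    """Relative percent at ``day``, linearly interpolated between observations.

    No extrapolation: ``day`` must lie within the observed range.
    """
    days = record.days
    if day < days[0] or day > days[-1]:
        raise ValueError(
            f"{record.animal_id}: day {day} outside observed range "
            f"[{days[0]}, {days[-1]}]"
        )
    rel = np.array([p for _, p in relative_series(record, quantity)])
    return float(np.interp(day, days, rel))


def group_summary(
    records: Sequence[AnimalRecord],
    day: float,
    quantity: Quantity = "tumor-volume",
) -> tuple[float, float, int]:
    """Group mean ± SD of per-animal relative values (percent of day 0).

    Averages the per-animal ratios (mean of ratios), the convention for
    relative tumor volume; sample SD (ddof=1), SD = 0 for a single animal.
    Animals whose observations do not bracket ``day`` raise.
    """
    if not records:
        raise ValueError("no records")
    rel = np.array([_relative_at_day(r, day, quantity) for r in records])
    sd = float(np.std(rel, ddof=1)) if rel.size > 1 else 0.0
    return float(np.mean(rel)), sd, int(rel.size)


def apply_endpoints(
    record: AnimalRecord,
    rules: EndpointRules = EndpointRules(),
    mode: Literal["analysis", "husbandry"] = "analysis",
) -> EndpointEvent:
    """First day on which an endpoint rule fires, else a censoring.

    Analysis mode uses the survival-analysis volume threshold (default
    500 mm³); husbandry mode the humane limit (800 mm³).  Both include the
    strict >20 % weight-loss rule.  Records that never trigger are censored
    at the earlier of the last observation and the study end; a recorded
    euthanasia for another reason (e.g. moribund state) censors at its day.
    """
    vol_limit = (
        rules.analysis_volume_mm3 if mode == "analysis" else rules.humane_volume_mm3
    )
    baseline_w = record.weights()[0]
    if baseline_w <= 0:
        raise ValueError(f"{record.animal_id}: zero baseline body weight")
    for obs, vol in zip(record.observations, record.volumes()):
        reasons = []
        if vol >= vol_limit:
            reasons.append("volume")
        loss = (baseline_w - obs.body_weight_g) / baseline_w
        if loss > rules.weight_loss_limit:
            reasons.append("weight")
        if reasons:
            return EndpointEvent(
                animal_id=record.animal_id,
                day=obs.day,
                status="event",
                reason="+".join(reasons),
            )
    if record.fate.status == "euthanized" and record.fate.day is not None:
        return EndpointEvent(
            animal_id=record.animal_id,
            day=min(record.fate.day, rules.study_end_day),
            status="censored",
            reason=record.fate.reason or "euthanized",
        )
    censor_day = min(float(record.days[-1]), rules.study_end_day)
    return EndpointEvent(
        animal_id=record.animal_id, day=censor_day, status="censored", reason="study-end"
    )


def determine_mtd(
    groups: Mapping[float, Sequence[AnimalRecord]],
    rules: EndpointRules = EndpointRules(),
) -> float | None:
    """Maximum tolerated dose from weight-loss outcomes.

    The MTD is the highest tested activity at which no animal's body-weight
    loss strictly exceeded the limit (default 20 % of baseline) at any
    observation.  Returns ``None`` when every nonzero activity failed (MTD
    below the lowest tested dose).
    """
    tested = sorted(a for a in groups if a > 0)
    if not tested:
        raise ValueError("need at least one nonzero-activity group")

    def group_fails(records: Sequence[AnimalRecord]) -> bool:
        for r in records:
            w = r.weights()
            if w[0] <= 0:
                raise ValueError(f"{r.animal_id}: zero baseline body weight")
            max_loss = float(np.max((w[0] - w) / w[0]))
            if max_loss > rules.weight_loss_limit:
                return True
        return False

    tolerated = [a for a in tested if not group_fails(groups[a])]
    return max(tolerated) if tolerated else None


# ---------------------------------------------------------------------------
# CSV I/O
#
# Columns: animal_id, group_mbq, day, length_mm, width_mm, weight_g and
# optional fate columns (fate, fate_day, fate_reason) repeated per row.


def read_animal_records(path: str | Path) -> list[AnimalRecord]:
    df = pd.read_csv(path, comment="#")
    required = {"animal_id", "group_mbq", "day", "length_mm", "width_mm", "weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("day")
        obs = [
            Observation(row.day, row.length_mm, row.width_mm, row.weight_g)
            for row in sub.itertuples()
        ]
        fate = Fate()
        if "fate" in sub.columns and isinstance(sub["fate"].iloc[-1], str):
            fate = Fate(
                status=sub["fate"].iloc[-1],
                day=(
                    float(sub["fate_day"].iloc[-1])
                    if "fate_day" in sub.columns and pd.notna(sub["fate_day"].iloc[-1])
                    else None
                ),
                reason=(
                    str(sub["fate_reason"].iloc[-1])
                    if "fate_reason" in sub.columns
                    and pd.notna(sub["fate_reason"].iloc[-1])
                    else ""
                ),
            )
        records.append(
            AnimalRecord(
                animal_id=str(animal_id),
                group_activity_mbq=float(sub["group_mbq"].iloc[0]),
                observations=obs,
                fate=fate,
            )
        )
    if not records:
        raise ValueError(f"{path}: no animal records")
    return records


def write_animal_records(records: Iterable[AnimalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        for o in r.observations:
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "group_mbq": r.group_activity_mbq,
                    "day": o.day,
                    "length_mm": o.length_mm,
                    "width_mm": o.width_mm,
                    "weight_g": o.body_weight_g,
                    "fate": r.fate.status,
                    "fate_day": r.fate.day if r.fate.day is not None else math.nan,
                    "fate_reason": r.fate.reason,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
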