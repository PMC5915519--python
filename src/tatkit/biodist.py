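"""Biodistribution tables and conversion to physical activity concentration.

A biodistribution study reports, per organ and sampling time, the percent of
the injected radioactivity dose per gram of tissue (%ID/g) — or, for very
small organs such as the thyroid, percent of injected dose in the whole organ
(%ID).  Values are conventionally decay-corrected to injection time.  For
dosimetry the decay correction must be undone so the curve reflects the
physical activity actually present in tissue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nuclide import DecayScheme, decay_factor

__all__ = [
    "TimeActivityTable",
    "ActivityConcentrationCurve",
    "BiodistributionError",
    "read_biodistribution",
    "write_biodistribution",
    "to_physical_concentration",
    "load_reference_biodistribution",
    "load_reference_dose_table",
]

PER_GRAM = "per_gram"
PER_ORGAN = "per_organ"
_VALID_UNITS = {PER_GRAM, PER_ORGAN}


class BiodistributionError(ValueError):
    """Validation failure in a biodistribution table; message lists cells."""


@dataclass
class ActivityConcentrationCurve:
    """Physical (not decay-corrected) activity concentration of one organ.

    ``activity_per_g[i]`` is the fraction of the injected activity present
    per gram of tissue at ``times_h[i]`` — dimensionless per gram, per unit
    injected activity.
    """

    organ: str
    times_h: np.ndarray
    activity_per_g: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activity_per_g = np.asarray(self.activity_per_g, dtype=float)
        if self.times_h.shape != self.activity_per_g.shape:
            raise BiodistributionError(
                f"{self.organ}: times and activities have different lengths"
            )
        if np.any(self.activity_per_g < 0):
            raise BiodistributionError(f"{self.organ}: negative activity values")


@dataclass
class TimeActivityTable:
    """Organ × time uptake table (mean, SD, n) with unit and decay flags.

    ``means``/``sds``/``n`` are DataFrames indexed by organ with the sampling
    times (hours) as columns.  ``units`` maps each organ to ``"per_gram"``
    (%ID/g) or ``"per_organ"`` (%ID, whole organ).  ``decay_corrected``
    records whether values are referred back to injection time (the usual
    reporting convention).
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    n: pd.DataFrame
    units: dict[str, str]
    decay_corrected: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def organs(self) -> list[str]:
        return list(self.means.index)

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(self.means.columns, dtype=float)

    def validate(self) -> None:
        problems: list[str] = []
        times = self.times_h
        if len(times) == 0 or len(self.means.index) == 0:
            problems.append("table has no organs or no time points")
        if np.any(np.diff(times) <= 0):
            problems.append(f"times not strictly increasing: {times.tolist()}")
        if np.any(times <= 0):
            problems.append(f"non-positive sampling times: {times.tolist()}")
        for organ in self.means.index:
            unit = self.units.get(organ)
            if unit not in _VALID_UNITS:
                problems.append(f"organ {organ!r}: missing or invalid unit flag {unit!r}")
            for t in self.means.columns:
                m = self.means.at[organ, t]
                s = self.sds.at[organ, t]
                if not np.isfinite(m) or m < 0:
                    problems.append(f"cell ({organ}, {t} h): invalid mean {m}")
                if not np.isfinite(s) or s < 0:
                    problems.append(f"cell ({organ}, {t} h): invalid sd {s}")
        if problems:
            raise BiodistributionError(
                "invalid biodistribution table:\n  " + "\n  ".join(problems)
            )

    def scaled(self, factor: float) -> "TimeActivityTable":
        """Return a copy with all means and SDs multiplied by ``factor``."""
        return TimeActivityTable(
            means=self.means * factor,
            sds=self.sds * factor,
            n=self.n.copy(),
            units=dict(self.units),
            decay_corrected=self.decay_corrected,
            meta=dict(self.meta),
        )


def _parse_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _split_pm(cell: str) -> tuple[float, float]:
    """Parse a ``"mean±sd"`` cell (also accepts ``+/-``)."""
    text = str(cell).replace("+/-", "±")
    if "±" in text:
        m, _, s = text.partition("±")
        return float(m), float(s)
    return float(text), 0.0


def read_biodistribution(path: str | Path) -> TimeActivityTable:
    """Read a long-format biodistribution CSV.

    Expected columns: ``organ, unit, time_h, mean, sd[, n]`` — or a single
    ``value`` column holding ``mean±sd`` cells.  Leading ``# key: value``
    comment lines carry table metadata; ``# decay_corrected: true|false``
    sets the decay flag (default true, the universal reporting convention).

    Raises
    ------
    BiodistributionError
        On empty files, negative values, non-increasing times or missing
        unit flags, listing every offending cell.
    """
    path = Path(path)
    meta = _parse_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise BiodistributionError(f"{path}: empty biodistribution file") from exc
    if df.empty:
        raise BiodistributionError(f"{path}: no data rows")

    required = {"organ", "unit", "time_h"}
    if not required.issubset(df.columns):
        raise BiodistributionError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "value" in df.columns and "mean" not in df.columns:
        parsed = df["value"].map(_split_pm)
        df = df.assign(mean=[p[0] for p in parsed], sd=[p[1] for p in parsed])
    if "mean" not in df.columns:
        raise BiodistributionError(f"{path}: need 'mean'/'sd' columns or a 'value' column")
    if "sd" not in df.columns:
        df["sd"] = 0.0
    if "n" not in df.columns:
        df["n"] = 1

    means = df.pivot_table(index="organ", columns="time_h", values="mean", sort=False)
    sds = df.pivot_table(index="organ", columns="time_h", values="sd", sort=False)
    counts = df.pivot_table(index="organ", columns="time_h", values="n", sort=False)
    means = means.reindex(columns=sorted(means.columns))
    sds = sds.reindex(index=means.index, columns=means.columns)
    counts = counts.reindex(index=means.index, columns=means.columns)

    units = {str(o): str(u) for o, u in zip(df["organ"], df["unit"])}
    decay_corrected = meta.get("decay_corrected", "true").lower() in ("true", "1", "yes")

    return TimeActivityTable(
        means=means,
        sds=sds,
        n=counts,
        units=units,
        decay_corrected=decay_corrected,
        meta=meta,
    )


def write_biodistribution(table: TimeActivityTable, path: str | Path) -> None:
    """Write a table in the long CSV format accepted by :func:`read_biodistribution`."""
    rows = []
    for organ in table.organs:
        for t in table.means.columns:
            rows.append(
                {
                    "organ": organ,
                    "unit": table.units[organ],
                    "time_h": float(t),
                    "mean": table.means.at[organ, t],
                    "sd": table.sds.at[organ, t],
                    "n": int(table.n.at[organ, t]),
                }
            )
    buf = io.StringIO()
    buf.write(f"# decay_corrected: {str(table.decay_corrected).lower()}\n")
    for key, value in table.meta.items():
        if key != "decay_corrected":
            buf.write(f"# {key}: {value}\n")
    pd.DataFrame(rows).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def to_physical_concentration(
    table: TimeActivityTable,
    organ: str,
    scheme: DecayScheme,
    organ_mass_g: float | None = None,
) -> ActivityConcentrationCurve:
    """Convert one organ row into physical fraction-of-injected-activity per gram.

    For decay-corrected tables, ``a(tᵢ) = mean(tᵢ)/100 × exp(−λ tᵢ)``; tables
    already holding physical values are only divided by 100.  Per-organ rows
    (%ID, e.g. thyroid) additionally require ``organ_mass_g`` to convert to a
    per-gram concentration.
    """
    if organ not in table.means.index:
        raise KeyError(f"organ {organ!r} not in table (has {table.organs})")
    unit = table.units[organ]
    values = table.means.loc[organ].to_numpy(dtype=float)
    times = table.times_h
    a = values / 100.0
    if unit == PER_ORGAN:
        if organ_mass_g is None or organ_mass_g <= 0:
            raise ValueError(
                f"organ {organ!r} is reported per whole organ (%ID); a positive "
                "organ mass in grams is required to convert to a per-gram curve"
            )
        a = a / organ_mass_g
    if table.decay_corrected:
        a = a * np.array([decay_factor(t, scheme.half_life_h) for t in times])
    return ActivityConcentrationCurve(organ=organ, times_h=times, activity_per_g=a)


# ---------------------------------------------------------------------------
# Packaged reference data


def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("tatkit").joinpath("data", name)))


def load_reference_biodistribution() -> TimeActivityTable:
    """Packaged ²¹¹At-MABG biodistribution table (PC12 tumor-bearing mice)."""
    return read_biodistribution(_data_path("table1_biodistribution.csv"))


def load_reference_dose_table() -> pd.Series:
    """Published absorbed-dose coefficients (Gy/MBq), indexed by organ.

    External reference values for comparison; this package computes its own
    coefficients from the biodistribution table.
    """
    df = pd.read_csv(_data_path("table2_absorbed_dose.csv"), comment="#")
    return df.set_index("organ")["dose_gy_per_mbq"]
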