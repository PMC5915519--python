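"""In-vitro assay reductions: survival fractions, positive-cell fractions, fits.

Clonogenic/metabolic survival (MTT absorbance) is normalised to the untreated
control; DNA double-strand-break burden is a positive-cell fraction from
comet-assay counts.  An optional monoexponential dose–response fit
S(c) = 100·exp(−k·c) summarises the kill rate per unit activity
concentration (kBq/mL); it is primarily exercised by the synthetic-data
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseTable",
    "MonoexpFit",
    "read_plate",
    "write_plate",
    "survival_fraction",
    "positive_fraction",
    "fit_monoexponential_survival",
]


@dataclass
class DoseResponseTable:
    """Replicate readouts by activity concentration (kBq/mL).

    ``data`` has columns ``concentration_kbq_ml``, ``replicate``, ``readout``.
    Concentrations must be non-negative; normalised quantities require a
    0-kBq/mL control.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concentration_kbq_ml", "replicate", "readout"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns {sorted(missing)}")
        if (self.data["concentration_kbq_ml"] < 0).any():
            raise ValueError("negative activity concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_kbq_ml"].unique())


def read_plate(path: str | Path) -> DoseResponseTable:
    return DoseResponseTable(pd.read_csv(path, comment="#"))


def write_plate(table: DoseResponseTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def survival_fraction(
    table: DoseResponseTable, blank: float = 0.0
) -> pd.DataFrame:
    """Mean ± SD survival as percent of the 0-kBq/mL control.

    ``100 × mean(readout at c) / mean(readout at control)`` per
    concentration; the control row maps to exactly 100 %.  ``blank`` is an
    optional background level subtracted from every readout before
    normalisation (off by default).

    Returns a DataFrame with columns ``concentration_kbq_ml, mean_pct,
    sd_pct, n``.
    """
    df = table.data.copy()
    df["readout"] = df["readout"] - blank
    control = df.loc[df["concentration_kbq_ml"] == 0, "readout"]
    if control.empty:
        raise ValueError("no 0-kBq/mL control wells present")
    c0 = control.mean()
    if c0 <= 0:
        raise ValueError(f"control mean readout must be positive, got {c0}")
    grouped = df.groupby("concentration_kbq_ml")["readout"]
    out = pd.DataFrame(
        {
            "concentration_kbq_ml": grouped.mean().index,
            "mean_pct": 100.0 * grouped.mean().to_numpy() / c0,
            "sd_pct": 100.0 * grouped.std(ddof=1).fillna(0.0).to_numpy() / c0,
            "n": grouped.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def positive_fraction(positives: int, total: int) -> float:
    """Percent of positive cells, 100 × positives / total."""
    if total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= positives <= total:
        raise ValueError(f"positives {positives} outside [0, {total}]")
    return 100.0 * positives / total


@dataclass
class MonoexpFit:
    k_per_kbq_ml: float
    fitted_pct: np.ndarray
    residuals_pct: np.ndarray

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_pct**2)))


def fit_monoexponential_survival(table: DoseResponseTable) -> MonoexpFit:
    """Least-squares fit of S(c) = 100·exp(−k·c) to the survival fractions.

    Requires at least three concentrations and strictly positive survival
    fractions.  Returns the kill rate k (per kBq/mL, constrained
    non-negative) with fitted values and residuals.
    """
    frac = survival_fraction(table)
    c = frac["concentration_kbq_ml"].to_numpy(dtype=float)
    s = frac["mean_pct"].to_numpy(dtype=float)
    if c.size < 3:
        raise ValueError("need at least three concentrations to fit")
    if np.any(s <= 0):
        raise ValueError("survival fractions must be positive to fit")

    # log-linear initial guess through the origin
    nz = c > 0
    k0 = max(0.0, float(-np.sum(c[nz] * np.log(s[nz] / 100.0)) / np.sum(c[nz] ** 2))) if nz.any() else 0.0

    def model(conc, k):
        return 100.0 * np.exp(-k * conc)

    popt, _ = curve_fit(model, c, s, p0=[k0], bounds=(0.0, np.inf))
    k = float(popt[0])
    fitted = model(c, k)
    return MonoexpFit(k_per_kbq_ml=k, fitted_pct=fitted, residuals_pct=s - fitted)
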