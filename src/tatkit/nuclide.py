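"""Radionuclide physics for alpha-emitter internal dosimetry.

A :class:`DecayScheme` carries the physical constants of an alpha-emitting
radionuclide: half-life and the alpha branches (branch fraction, alpha energy
in MeV).  For ²¹¹At the two branches are the direct alpha (41.8 %, 5.867 MeV)
and the alpha emitted via the 0.52-s daughter ²¹¹Po (58.2 %, 7.450 MeV); the
daughter is treated as decaying in place instantaneously, which is negligible
at hour-scale biodistribution sampling.  Electron-capture photon/electron
emissions and the long-lived ²⁰⁷Bi granddaughter are excluded: only the
locally deposited alpha energy enters the dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "DecayScheme",
    "AT211",
    "MEV_TO_JOULE",
    "decay_factor",
    "mean_alpha_energy",
    "apply_decay",
    "load_scheme",
]

#: Joules per MeV (CODATA exact).
MEV_TO_JOULE = 1.602176634e-13

_BRANCH_SUM_TOL = 1e-6


@dataclass(frozen=True)
class DecayScheme:
    """Physical constants of an alpha-emitting radionuclide.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"At-211"``.
    half_life_h : float
        Physical half-life in hours; must be positive.
    branches : tuple of (float, float)
        ``(branch_fraction, alpha_energy_mev)`` pairs.  Fractions lie in
        [0, 1] and sum to at most 1 (within tolerance); energies are
        non-negative.
    """

    name: str
    half_life_h: float
    branches: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be positive, got {self.half_life_h}")
        if len(self.branches) == 0:
            raise ValueError("a decay scheme needs at least one alpha branch")
        total = 0.0
        for frac, energy in self.branches:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"branch fraction {frac} outside [0, 1]")
            if energy < 0:
                raise ValueError(f"negative alpha energy {energy} MeV")
            total += frac
        if total > 1.0 + _BRANCH_SUM_TOL:
            raise ValueError(f"branch fractions sum to {total} > 1")
        # normalise storage so equality/hash are well defined
        object.__setattr__(
            self, "branches", tuple((float(f), float(e)) for f, e in self.branches)
        )

    @property
    def decay_constant_per_h(self) -> float:
        """λ = ln2 / t½, per hour."""
        return math.log(2.0) / self.half_life_h


#: Default ²¹¹At scheme (standard nuclear data; configurable, not asserted
#: by any single publication).
AT211 = DecayScheme(
    name="At-211",
    half_life_h=7.214,
    branches=((0.418, 5.867), (0.582, 7.450)),
)


def decay_factor(t_h: float, half_life_h: float) -> float:
    """Fraction of activity remaining after ``t_h`` hours.

    Returns ``exp(−ln2 · t / t½)``, in (0, 1].

    Raises
    ------
    ValueError
        If the half-life is non-positive or ``t_h`` is negative.
    """
    if not half_life_h > 0:
        raise ValueError(f"half_life_h must be positive, got {half_life_h}")
    if t_h < 0:
        raise ValueError(f"t_h must be non-negative, got {t_h}")
    return math.exp(-math.log(2.0) * t_h / half_life_h)


def mean_alpha_energy(scheme: DecayScheme) -> float:
    """Branch-weighted mean alpha energy per decay, in joules.

    ``Σ branch_fraction × alpha_energy``, converted MeV → J.  For the ²¹¹At
    default this is 0.418·5.867 + 0.582·7.450 ≈ 6.788 MeV ≈ 1.088e−12 J.
    """
    mev = sum(frac * energy for frac, energy in scheme.branches)
    return mev * MEV_TO_JOULE


def apply_decay(
    value: float,
    t_h: float,
    scheme: DecayScheme,
    direction: Literal["correct", "uncorrect"] = "correct",
) -> float:
    """Decay-correct or decay-uncorrect an activity-like quantity.

    ``correct`` divides by the decay factor (refers the measurement back to
    injection time); ``uncorrect`` multiplies (restores the physical activity
    at time ``t_h``).  The two directions are exact inverses.
    """
    f = decay_factor(t_h, scheme.half_life_h)
    if direction == "correct":
        return value / f
    if direction == "uncorrect":
        return value * f
    raise ValueError(f"direction must be 'correct' or 'uncorrect', got {direction!r}")


def load_scheme(path: str | Path) -> DecayScheme:
    """Load a decay scheme from a YAML config file.

    Expected keys: ``name``, ``half_life_h``, ``branches`` (list of
    ``[fraction, energy_mev]`` pairs).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"decay scheme config {path} is not a mapping")
    try:
        return DecayScheme(
            name=str(raw["name"]),
            half_life_h=float(raw["half_life_h"]),
            branches=tuple((float(f), float(e)) for f, e in raw["branches"]),
        )
    except KeyError as exc:
        raise ValueError(f"decay scheme config {path} missing key {exc}") from exc
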