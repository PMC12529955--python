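"""Core surface pressure–area (π–A) isotherm analysis.

A Langmuir-trough compression experiment records surface pressure π
(mN/m) against mean molecular area A (Å²/molecule).  This module holds
the :class:`Isotherm` container and the standard scalar/curve quantities
derived from a single compression branch:

* the compression (elasticity) modulus ``Cs⁻¹ = −A·(dπ/dA)``,
* the 2D phase implied by a modulus value (gas, liquid-expanded,
  liquid-condensed, solid),
* the lift-off area where pressure first rises above baseline,
* the interpolated molecular area at a chosen surface pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Isotherm",
    "ModulusCurve",
    "PhaseLabel",
    "AreaAtPressure",
    "clean_branch",
    "compression_modulus",
    "classify_phase",
    "lift_off_area",
    "area_at_pressure",
]


class IsothermError(ValueError):
    """Raised for traces that violate an operation's preconditions."""


@dataclass
class Isotherm:
    """One branch (or raw trace) of a π–A isotherm.

    Parameters
    ----------
    area:
        Mean molecular area, Å²/molecule. Strictly positive.
    pressure:
        Surface pressure, mN/m. Finite.
    temperature:
        Subphase temperature in K (default 294 K, i.e. 21 °C).
    subphase:
        Free-text label of the subphase (e.g. ``"water"``, ``"PTX+EPI"``).
    metadata:
        Arbitrary provenance; generators store their ground-truth
        parameters here.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 294.0
    subphase: str = "water"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.ndim != 1 or self.area.shape != self.pressure.shape:
            raise IsothermError("area and pressure must be 1-D and equal length")
        if not np.all(np.isfinite(self.area)) or not np.all(np.isfinite(self.pressure)):
            raise IsothermError("non-finite values in isotherm trace")
        if np.any(self.area <= 0):
            raise IsothermError("molecular areas must be strictly positive")

    def __len__(self) -> int:
        return self.area.size


class PhaseLabel(IntEnum):
    """2D monolayer phase, ordered by increasing condensation."""

    G = 0   # gas
    LE = 1  # liquid-expanded
    LC = 2  # liquid-condensed
    S = 3   # solid


@dataclass
class ModulusCurve:
    """Compression modulus Cs⁻¹ evaluated along an isotherm branch."""

    pressure: np.ndarray   # mN/m, grid where the derivative is estimable
    csinv: np.ndarray      # mN/m
    area: np.ndarray       # Å²/molecule at the same grid points

    def max_modulus(self) -> float:
        return float(np.max(self.csinv))


class AreaAtPressure(NamedTuple):
    """Interpolated area with a plateau-ambiguity flag."""

    area: float
    ambiguous: bool


def clean_branch(iso: Isotherm) -> Isotherm:
    """Merge duplicate-area rows and enforce monotone (decreasing) area.

    Rows sharing the same area are collapsed to their mean pressure; the
    result is sorted by decreasing area, as recorded on compression.  The
    original trace is kept under ``metadata["raw"]``.

    Raises
    ------
    IsothermError
        If fewer than 3 distinct areas remain.
    """
    areas, inverse = np.unique(iso.area, return_inverse=True)
    if areas.size < 3:
        raise IsothermError("need at least 3 distinct areas to form a branch")
    pi = np.zeros_like(areas)
    counts = np.bincount(inverse, minlength=areas.size)
    np.add.at(pi, inverse, iso.pressure)
    pi /= counts
    order = np.argsort(areas)[::-1]
    meta = dict(iso.metadata)
    meta["raw"] = (iso.area.copy(), iso.pressure.copy())
    return replace(iso, area=areas[order], pressure=pi[order], metadata=meta)


def _is_monotone(a: np.ndarray) -> bool:
    d = np.diff(a)
    return bool(np.all(d < 0) or np.all(d > 0))


def compression_modulus(iso: Isotherm, window: int = 11, polyorder: int = 2) -> ModulusCurve:
    """Compression modulus Cs⁻¹(π) = −A·(dπ/dA) along a cleaned branch.

    The derivative dπ/dA is estimated by a local least-squares polynomial
    (Savitzky–Golay style) of order ``polyorder`` over ``window``
    consecutive points centred on each interior sample; raw finite
    differences on trough data are too noisy to be useful.

    Parameters
    ----------
    iso:
        Cleaned branch with strictly monotone area, ≥ 5 points.
    window:
        Odd number of points in the local fit (default 11; shrunk to the
        largest odd value ≤ len(iso) when the trace is short).
    """
    if len(iso) < 5:
        raise IsothermError("need at least 5 points for differentiation")
    if not _is_monotone(iso.area):
        raise IsothermError("area is not monotone; run clean_branch first")
    if window % 2 == 0:
        raise IsothermError("window must be odd")
    window = min(window, len(iso) if len(iso) % 2 == 1 else len(iso) - 1)
    half = window // 2
    n = len(iso)
    idx = np.arange(half, n - half)
    csinv = np.empty(idx.size)
    for j, i in enumerate(idx):
        a = iso.area[i - half : i + half + 1]
        p = iso.pressure[i - half : i + half + 1]
        # centre areas for conditioning; derivative of the local polynomial
        coef = np.polyfit(a - a.mean(), p, polyorder)
        dpda = np.polyval(np.polyder(coef), iso.area[i] - a.mean())
        csinv[j] = -iso.area[i] * dpda
    return ModulusCurve(pressure=iso.pressure[idx], csinv=csinv, area=iso.area[idx])


def classify_phase(csinv: float) -> PhaseLabel:
    """Map a compression-modulus value (mN/m) to its 2D phase.

    Ranges: G [0, 12.5), LE [12.5, 100), LC [100, 250], S (250, ∞).
    Boundary values go to the higher phase at 12.5 and 100, and to LC at
    exactly 250.
    """
    if not np.isfinite(csinv) or csinv < 0:
        raise IsothermError(f"compression modulus must be >= 0, got {csinv}")
    if csinv < 12.5:
        return PhaseLabel.G
    if csinv < 100.0:
        return PhaseLabel.LE
    if csinv <= 250.0:
        return PhaseLabel.LC
    return PhaseLabel.S


def lift_off_area(iso: Isotherm, threshold: float = 0.5) -> float:
    """Largest area (Å²) at which π first exceeds ``threshold`` mN/m.

    Scanned from large to small area along the compression branch; the
    crossing is linearly interpolated.  The default threshold of
    0.5 mN/m sits well above typical trough noise (±0.1 mN/m).
    """
    order = np.argsort(iso.area)[::-1]
    a, p = iso.area[order], iso.pressure[order]
    above = p > threshold
    if not above.any():
        raise IsothermError(f"pressure never exceeds {threshold} mN/m")
    i = int(np.argmax(above))
    if i == 0:
        return float(a[0])
    # interpolate between the last sub-threshold and first supra-threshold point
    f = (threshold - p[i - 1]) / (p[i] - p[i - 1])
    return float(a[i - 1] + f * (a[i] - a[i - 1]))


def area_at_pressure(iso: Isotherm, pi_target: float) -> AreaAtPressure:
    """Interpolated molecular area at a target surface pressure.

    Walks the compression branch from large to small area and linearly
    interpolates A at the *first* crossing of ``pi_target``.  In an LE–LC
    coexistence plateau the same pressure is met more than once; the
    first crossing is returned and ``ambiguous`` is set.
    """
    order = np.argsort(iso.area)[::-1]
    a, p = iso.area[order], iso.pressure[order]
    if not (p.min() <= pi_target <= p.max()):
        raise IsothermError(
            f"target pressure {pi_target} outside trace range [{p.min():.3g}, {p.max():.3g}]"
        )
    crossings = []
    for i in range(p.size - 1):
        lo, hi = sorted((p[i], p[i + 1]))
        if lo <= pi_target <= hi and p[i] != p[i + 1]:
            f = (pi_target - p[i]) / (p[i + 1] - p[i])
            crossings.append(float(a[i] + f * (a[i + 1] - a[i])))
        elif p[i] == pi_target == p[i + 1]:
            crossings.append(float(a[i]))
    if not crossings:
        # target equals an isolated sample exactly
        j = int(np.argmin(np.abs(p - pi_target)))
        return AreaAtPressure(float(a[j]), False)
    # crossings separated by more than interpolation jitter ⇒ plateau
    ambiguous = (max(crossings) - min(crossings)) > 1e-9
    return AreaAtPressure(crossings[0], ambiguous)
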