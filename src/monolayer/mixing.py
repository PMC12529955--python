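"""Mixing thermodynamics and the two-drug synergy statistic.

For a mixed monolayer the ideal (additive) area at a given surface
pressure is the mole-fraction weighted sum of the pure-component areas,
``A_id = Σ A_i·X_i``; the excess area ``A_exc = A_mix − A_id`` signals
attractive (negative) or repulsive (positive) inter-component
interactions.

For drugs dissolved in the subphase, the per-drug area shift at pressure
π is ``ΔA_drug(π) = A_drug(π) − A_water(π)``.  Synergy of a drug pair is
declared when the shift produced by the mixture exceeds the sum of the
single-drug shifts at the same pressure; the margin is compared against
the quadrature-propagated uncertainty of the three measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .isotherm import Isotherm, IsothermError, area_at_pressure

__all__ = [
    "MixtureSpec",
    "AreaShiftTable",
    "SynergyResult",
    "ideal_area",
    "excess_area",
    "drug_area_shift",
    "assess_synergy",
]


@dataclass
class MixtureSpec:
    """Named components with mole fractions summing to 1."""

    components: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.components) != self.fractions.size:
            raise ValueError("one mole fraction per component required")
        if np.any(self.fractions < 0):
            raise ValueError("mole fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {self.fractions.sum()}, not 1")


def ideal_area(component_areas: Sequence[float], mix: MixtureSpec) -> float:
    """Ideal-mixing area A_id = Σ A_i·X_i at a common surface pressure (Å²)."""
    areas = np.asarray(component_areas, dtype=float)
    if areas.size != mix.fractions.size:
        raise ValueError(
            f"{areas.size} areas for {mix.fractions.size} components"
        )
    return float(areas @ mix.fractions)


def excess_area(a_mixed: float, a_ideal: float) -> float:
    """Excess area A_exc = A_mix − A_id (Å²); negative means net attraction."""
    if not (np.isfinite(a_mixed) and np.isfinite(a_ideal)):
        raise ValueError("areas must be finite")
    return float(a_mixed - a_ideal)


def drug_area_shift(
    iso_drug: Isotherm, iso_water: Isotherm, pressures: Sequence[float]
) -> np.ndarray:
    """Per-pressure area shift ΔA(π) = A_drug(π) − A_water(π), Å²/molecule.

    Both traces must cover every requested pressure; the failing trace is
    named in the error.  Evaluated on the compression branch via
    :func:`monolayer.isotherm.area_at_pressure`.
    """
    out = np.empty(len(pressures))
    for i, pi in enumerate(pressures):
        try:
            a_drug = area_at_pressure(iso_drug, pi).area
        except IsothermError as exc:
            raise IsothermError(f"drug trace ({iso_drug.subphase}): {exc}") from exc
        try:
            a_water = area_at_pressure(iso_water, pi).area
        except IsothermError as exc:
            raise IsothermError(f"water trace ({iso_water.subphase}): {exc}") from exc
        out[i] = a_drug - a_water
    return out


@dataclass
class AreaShiftTable:
    """Area shifts of two single drugs and their mixture on one π grid."""

    pressures: np.ndarray         # mN/m
    shift_a: np.ndarray           # ΔA of drug A, Å²
    shift_b: np.ndarray           # ΔA of drug B, Å²
    shift_mix: np.ndarray         # ΔA of the drug mixture, Å²
    labels: tuple[str, str, str] = ("PTX", "EPI", "PTX+EPI")

    def __post_init__(self) -> None:
        arrs = [np.atleast_1d(np.asarray(a, dtype=float))
                for a in (self.pressures, self.shift_a, self.shift_b, self.shift_mix)]
        self.pressures, self.shift_a, self.shift_b, self.shift_mix = arrs
        n = self.pressures.size
        if any(a.size != n for a in arrs[1:]):
            raise ValueError("all shift columns must match the pressure grid")

    @classmethod
    def from_isotherms(
        cls,
        iso_water: Isotherm,
        iso_a: Isotherm,
        iso_b: Isotherm,
        iso_mix: Isotherm,
        pressures: Sequence[float],
        labels: tuple[str, str, str] = ("PTX", "EPI", "PTX+EPI"),
    ) -> "AreaShiftTable":
        return cls(
            pressures=np.asarray(pressures, dtype=float),
            shift_a=drug_area_shift(iso_a, iso_water, pressures),
            shift_b=drug_area_shift(iso_b, iso_water, pressures),
            shift_mix=drug_area_shift(iso_mix, iso_water, pressures),
            labels=labels,
        )


@dataclass
class SynergyResult:
    """Synergy assessment at one surface pressure.

    ``margin = ΔA_mix − (ΔA_a + ΔA_b)``; synergy is flagged when the
    margin exceeds ``k`` times the quadrature uncertainty.  The k-sigma
    rule is this package's convention — the underlying experimental
    criterion is stated without a significance test.
    """

    pressure: float
    shift_mix: float
    shift_sum: float
    margin: float
    uncertainty: float
    synergy: bool
    k: float = 1.0
    note: str = field(default="flag rule margin > k·sigma is a package convention")


def assess_synergy(
    table: AreaShiftTable,
    uncertainties: Sequence[Sequence[float]] | np.ndarray | None = None,
    k: float = 1.0,
) -> list[SynergyResult]:
    """Evaluate the mixed-drug synergy criterion at every table pressure.

    Parameters
    ----------
    table:
        Area shifts of drug A, drug B and the mixture on a common grid.
    uncertainties:
        Per-pressure standard deviations ``(σ_a, σ_b, σ_mix)`` in Å²;
        zeros when omitted.  Propagated in quadrature.
    k:
        Flag threshold in units of the propagated uncertainty.
    """
    n = table.pressures.size
    if uncertainties is None:
        sig = np.zeros((n, 3))
    else:
        sig = np.asarray(uncertainties, dtype=float).reshape(n, 3)
    results = []
    for i in range(n):
        s_sum = float(table.shift_a[i] + table.shift_b[i])
        margin = float(table.shift_mix[i] - s_sum)
        unc = float(np.sqrt(np.sum(sig[i] ** 2)))
        results.append(
            SynergyResult(
                pressure=float(table.pressures[i]),
                shift_mix=float(table.shift_mix[i]),
                shift_sum=s_sum,
                margin=margin,
                uncertainty=unc,
                synergy=margin > k * unc,
                k=k,
            )
        )
    return results
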