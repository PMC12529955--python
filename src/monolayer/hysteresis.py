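"""Thermodynamics of compression–expansion hysteresis.

A compression–expansion cycle of a Langmuir monolayer is generally
lossy: the expansion branch runs at smaller areas than the compression
branch.  Three state-function differences quantify the loss over a
pressure window [π_low, π_high] (1 and 30 mN/m by default):

* branch free energy  ``ΔG = N_A ∫ A dπ``  (trapezoid rule, converted
  from mN/m·Å² per molecule to kcal/mol),
* hysteresis free energy  ``ΔG_hys = ΔG_exp − ΔG_comp``,
* hysteresis entropy  ``ΔS_hys = Σ_π R·ln(A_exp(π)/A_comp(π))`` summed
  over a fixed pressure grid (default 1 mN/m steps, 30 terms — the grid
  density scales the magnitude, so it is an explicit parameter),
* hysteresis enthalpy  ``ΔH_hys = ΔG_hys + T·ΔS_hys``.

A reversible cycle (identical branches) gives exactly zero for all
three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isotherm import Isotherm, IsothermError

__all__ = [
    "CompressionCycle",
    "HysteresisThermo",
    "split_cycles",
    "branch_free_energy",
    "hysteresis_free_energy",
    "hysteresis_entropy",
    "hysteresis_enthalpy",
    "analyze_cycle",
]

#: kcal/mol per (mN/m · Å²/molecule): 1e-3 N/m · 1e-20 m² · N_A / 4184 J/kcal
KCAL_PER_MNM_A2 = 1e-23 * 6.02214076e23 / 4184.0  # 1.43933e-3

#: gas constant in kcal/(mol·K)
R_KCAL = 1.9872e-3


@dataclass
class CompressionCycle:
    """One compression branch and the following expansion branch."""

    compression: Isotherm  # recorded with decreasing area
    expansion: Isotherm    # recorded with increasing area
    index: int = 0
    temperature: float = 294.0


def split_cycles(iso: Isotherm) -> list[CompressionCycle]:
    """Split a time-ordered trace into compression–expansion cycles.

    The trace is cut at area extrema; a branch with decreasing area is a
    compression, the following increasing branch its expansion.
    """
    a = iso.area
    d = np.sign(np.diff(a))
    # run-length scan over nonzero barrier directions
    dirs = d[d != 0]
    if dirs.size == 0 or np.all(dirs == dirs[0]):
        raise IsothermError("no barrier direction reversal found in trace")
    breakpoints = [0]
    cur = d[np.argmax(d != 0)]
    for i in range(d.size):
        if d[i] != 0 and d[i] != cur:
            breakpoints.append(i)
            cur = d[i]
    breakpoints.append(a.size - 1)

    branches = []
    for s, e in zip(breakpoints[:-1], breakpoints[1:]):
        seg = slice(s, e + 1)
        direction = np.sign(a[e] - a[s])
        branches.append(
            (
                direction,
                Isotherm(
                    a[seg], iso.pressure[seg], iso.temperature, iso.subphase,
                    dict(iso.metadata),
                ),
            )
        )
    cycles = []
    i = 0
    idx = 0
    while i + 1 < len(branches):
        if branches[i][0] < 0 and branches[i + 1][0] > 0:
            cycles.append(
                CompressionCycle(
                    compression=branches[i][1],
                    expansion=branches[i + 1][1],
                    index=idx,
                    temperature=iso.temperature,
                )
            )
            idx += 1
            i += 2
        else:
            i += 1
    if not cycles:
        raise IsothermError("trace contains no full compression–expansion cycle")
    return cycles


def branch_free_energy(
    branch: Isotherm, pi_low: float = 1.0, pi_high: float = 30.0
) -> float:
    """Free energy of one branch, ``N_A ∫ A dπ`` over [π_low, π_high], kcal/mol."""
    if pi_high < pi_low:
        raise IsothermError("pi_high must be >= pi_low")
    if pi_high == pi_low:
        return 0.0
    order = np.argsort(branch.pressure)
    p = branch.pressure[order]
    a = branch.area[order]
    if pi_low < p[0] or pi_high > p[-1]:
        raise IsothermError(
            f"branch covers [{p[0]:.3g}, {p[-1]:.3g}] mN/m, "
            f"not the integration limits [{pi_low}, {pi_high}]"
        )
    inside = (p > pi_low) & (p < pi_high)
    grid = np.concatenate(([pi_low], p[inside], [pi_high]))
    areas = np.interp(grid, p, a)
    integral = np.trapezoid(areas, grid)  # mN/m · Å²
    return float(integral * KCAL_PER_MNM_A2)


def hysteresis_free_energy(
    cycle: CompressionCycle, pi_low: float = 1.0, pi_high: float = 30.0
) -> float:
    """ΔG_hys = ΔG_exp − ΔG_comp (kcal/mol); ≤ 0 for a lossy cycle."""
    return branch_free_energy(cycle.expansion, pi_low, pi_high) - branch_free_energy(
        cycle.compression, pi_low, pi_high
    )


def hysteresis_entropy(
    cycle: CompressionCycle,
    grid_step: float = 1.0,
    pi_low: float = 1.0,
    pi_high: float = 30.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Hysteresis entropy summed over a fixed pressure grid.

    Returns ``(T·ΔS_hys in kcal/mol, grid pressures, per-π T·ΔS terms)``.
    The per-pressure term is ``R·ln(A_exp(π)/A_comp(π))``; with the
    default 1 mN/m step over [1, 30] the sum has 30 terms.
    """
    if grid_step <= 0:
        raise IsothermError("grid_step must be positive")
    grid = np.arange(pi_low, pi_high + grid_step / 2, grid_step)
    a_comp = _interp_branch(cycle.compression, grid, "compression")
    a_exp = _interp_branch(cycle.expansion, grid, "expansion")
    ratio = a_exp / a_comp
    if np.any(ratio <= 0):
        raise IsothermError("non-positive area ratio on entropy grid")
    terms = R_KCAL * np.log(ratio)  # ΔS_π in kcal/(mol·K)
    t_ds = float(cycle.temperature * np.sum(terms))
    return t_ds, grid, cycle.temperature * terms


def _interp_branch(branch: Isotherm, grid: np.ndarray, name: str) -> np.ndarray:
    order = np.argsort(branch.pressure)
    p = branch.pressure[order]
    a = branch.area[order]
    if grid[0] < p[0] or grid[-1] > p[-1]:
        raise IsothermError(f"{name} branch does not span the entropy grid")
    return np.interp(grid, p, a)


def hysteresis_enthalpy(dg_hys: float, t_ds_hys: float) -> float:
    """ΔH_hys = ΔG_hys + T·ΔS_hys (kcal/mol)."""
    return float(dg_hys + t_ds_hys)


@dataclass
class HysteresisThermo:
    """All hysteresis state functions of one cycle (kcal/mol)."""

    dg_comp: float
    dg_exp: float
    dg_hys: float
    t_ds_hys: float
    dh_hys: float
    temperature: float
    pi_limits: tuple[float, float]
    grid_step: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.dg_hys - (self.dg_exp - self.dg_comp)) > 1e-9:
            raise ValueError("dg_hys must equal dg_exp - dg_comp")
        if abs(self.dh_hys - (self.dg_hys + self.t_ds_hys)) > 1e-9:
            raise ValueError("dh_hys must equal dg_hys + t_ds_hys")


def analyze_cycle(
    cycle: CompressionCycle,
    pi_low: float = 1.0,
    pi_high: float = 30.0,
    grid_step: float = 1.0,
) -> HysteresisThermo:
    """Compute every hysteresis state function for one cycle."""
    dg_comp = branch_free_energy(cycle.compression, pi_low, pi_high)
    dg_exp = branch_free_energy(cycle.expansion, pi_low, pi_high)
    dg_hys = dg_exp - dg_comp
    t_ds, _, _ = hysteresis_entropy(cycle, grid_step, pi_low, pi_high)
    return HysteresisThermo(
        dg_comp=dg_comp,
        dg_exp=dg_exp,
        dg_hys=dg_hys,
        t_ds_hys=t_ds,
        dh_hys=hysteresis_enthalpy(dg_hys, t_ds),
        temperature=cycle.temperature,
        pi_limits=(pi_low, pi_high),
        grid_step=grid_step,
    )
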