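"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one class of experimental input and embeds its
parameters in the output metadata, so analysis↔generation round trips
are self-describing:

* :func:`gen_isotherm` — piecewise-smooth π–A compression branches with
  a programmable lift-off area, an LE–LC coexistence plateau, a steep
  condensed rise and optional drug-induced area shifts;
* :func:`gen_cycle` — compression–expansion cycles whose expansion
  branch is an area-ratio image of the compression branch, optionally
  solved for a target hysteresis entropy;
* :func:`gen_map` — diffraction maps as Lorentzian(Qxy)×Gaussian(Qz)
  peaks over a smooth background with optional Poisson counting noise;
* :func:`gen_frames` — monolayer configuration frames with prescribed
  chain tilt, drug clusters of known spacing and an exactly countable
  hydrogen-bond set;
* :func:`gen_polarized_pair` — s/p polarized band spectra computed from
  the same two-phase ATR optical model the analysis inverts.

Default parameter values follow the studied systems: 294 K, an
8×8×25.5 nm box with 80/80/40 lipid molecules, lift-off near 70 Å² with
a drug-shifted variant near 130 Å², LE–LC plateaus near 10 and
30 mN/m.  All randomness is drawn from a seeded generator; the same
seed reproduces a byte-identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import atr
from .gixd import GIXDMap
from .hysteresis import R_KCAL, CompressionCycle
from .isotherm import Isotherm
from .traj import Frame

__all__ = [
    "IsothermParams",
    "CycleParams",
    "MapParams",
    "FrameParams",
    "SpectrumParams",
    "gen_isotherm",
    "gen_cycle",
    "cycle_trace",
    "gen_map",
    "gen_frames",
    "gen_polarized_pair",
    "MAP_PRESETS",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class IsothermParams:
    """Ground truth of one synthetic compression branch.

    ``area_shift`` displaces the whole curve along A: a scalar applies a
    constant offset; a list of ``(π, ΔA)`` pairs is linearly
    interpolated in pressure (drug-incorporation phenomenology).
    """

    lift_off: float = 70.0          # Å²/molecule
    slope_le: float = 2.0           # mN/m per Å² in the expanded phase
    plateau_pressure: float = 10.0  # mN/m
    plateau_width: float = 10.0     # Å²
    slope_plateau: float = 0.05     # residual slope inside the plateau
    slope_lc: float = 8.0           # mN/m per Å² in the condensed phase
    collapse_pressure: float = 55.0  # mN/m
    area_shift: float | list[tuple[float, float]] = 0.0
    noise_sigma: float = 0.0        # mN/m, additive Gaussian
    blend_width: float = 0.4        # Å², logistic blending of segments
    n_points: int = 400
    area_max: float | None = None   # defaults to lift_off * 1.3
    temperature: float = 294.0
    subphase: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_pressure >= self.collapse_pressure:
            raise ValueError("plateau pressure must be below collapse pressure")
        if min(self.slope_le, self.slope_lc, self.slope_plateau) <= 0:
            raise ValueError("slopes must be positive")
        if self.lift_off <= 0 or self.plateau_width <= 0:
            raise ValueError("lift_off and plateau_width must be positive")


def gen_isotherm(p: IsothermParams) -> Isotherm:
    """Synthesise one compression branch from :class:`IsothermParams`.

    The magnitude of dπ/dA is a logistic blend of the three segment
    slopes (expanded / plateau / condensed); pressure is the cumulative
    integral from the lift-off area downward and exactly 0 above it.
    """
    rng = np.random.default_rng(p.seed)
    a_max = p.area_max if p.area_max is not None else p.lift_off * 1.3
    # plateau location along the unshifted curve
    a1 = p.lift_off - p.plateau_pressure / p.slope_le   # plateau onset
    a2 = a1 - p.plateau_width                           # plateau end
    if a2 <= 0:
        raise ValueError("plateau extends below zero area")

    # fine grid for the pressure integral, descending in area
    fine = np.linspace(a_max, max(a2 - 60.0, 1.0), 6000)
    slope = (
        p.slope_plateau
        + (p.slope_le - p.slope_plateau) * _sigmoid((fine - a1) / p.blend_width)
        + (p.slope_lc - p.slope_plateau) * _sigmoid((a2 - fine) / p.blend_width)
    )
    slope[fine > p.lift_off] = 0.0
    # π grows as A decreases: integrate -slope dA from the top
    pi_fine = np.concatenate(
        ([0.0], np.cumsum(-slope[1:] * np.diff(fine)))
    )
    keep = pi_fine <= p.collapse_pressure
    fine, pi_fine = fine[keep], pi_fine[keep]

    idx = np.linspace(0, fine.size - 1, p.n_points).astype(int)
    area = fine[idx]
    pressure = pi_fine[idx]
    if p.area_shift:
        if np.isscalar(p.area_shift):
            area = area + float(p.area_shift)
        else:
            table = np.asarray(p.area_shift, dtype=float)
            order = np.argsort(table[:, 0])
            area = area + np.interp(pressure, table[order, 0], table[order, 1])
    if p.noise_sigma > 0:
        pressure = pressure + rng.normal(0.0, p.noise_sigma, pressure.size)
    return Isotherm(
        area=area,
        pressure=pressure,
        temperature=p.temperature,
        subphase=p.subphase,
        metadata={"ground_truth": asdict(p)},
    )


@dataclass
class CycleParams:
    """Ground truth of one compression–expansion cycle.

    The expansion branch is ``A_exp(π) = r(π)·A_comp(π)``; ``ratio`` is
    either a constant or ``(r_at_pi_low, r_at_pi_high)`` interpolated
    linearly in pressure.  When ``target_t_ds`` (kcal/mol) is given, a
    constant ratio is solved from the hysteresis-entropy formula:
    ``r = exp(TΔS / (T · n_grid · R))``.
    """

    base: IsothermParams = field(default_factory=lambda: IsothermParams(collapse_pressure=32.0))
    ratio: float | tuple[float, float] = 1.0
    target_t_ds: float | None = None   # kcal/mol
    pi_low: float = 1.0
    pi_high: float = 30.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        r = self.ratio if np.isscalar(self.ratio) else max(self.ratio)
        if self.target_t_ds is None and not (0 < min(np.atleast_1d(self.ratio)) <= 1 and r <= 1):
            raise ValueError("area ratio must lie in (0, 1]")
        if self.target_t_ds is not None and self.target_t_ds > 0:
            raise ValueError("target hysteresis entropy must be <= 0")


def gen_cycle(p: CycleParams) -> CompressionCycle:
    """Synthesise one cycle with a programmable hysteresis entropy."""
    base = IsothermParams(**{**asdict(p.base), "seed": p.seed})
    comp = gen_isotherm(base)
    if p.target_t_ds is not None:
        n_grid = int(round((p.pi_high - p.pi_low) / p.grid_step)) + 1
        r = math.exp(p.target_t_ds / (base.temperature * n_grid * R_KCAL))
        ratio = np.full(comp.pressure.size, r)
    elif np.isscalar(p.ratio):
        ratio = np.full(comp.pressure.size, float(p.ratio))
    else:
        r_lo, r_hi = p.ratio
        ratio = np.interp(comp.pressure, [p.pi_low, p.pi_high], [r_lo, r_hi])
    exp_area = comp.area * ratio
    meta = {"ground_truth": {**asdict(p), "base": asdict(p.base), "ratio_used": ratio.tolist()}}
    expansion = Isotherm(
        area=exp_area[::-1],
        pressure=comp.pressure[::-1],
        temperature=base.temperature,
        subphase=base.subphase,
        metadata=meta,
    )
    comp.metadata.update(meta)
    return CompressionCycle(
        compression=comp, expansion=expansion, index=0, temperature=base.temperature
    )


def cycle_trace(cycle: CompressionCycle, n_cycles: int = 1) -> Isotherm:
    """Concatenate a cycle into one time-ordered trace (for split tests)."""
    a = np.concatenate([cycle.compression.area, cycle.expansion.area])
    p = np.concatenate([cycle.compression.pressure, cycle.expansion.pressure])
    a = np.tile(a, n_cycles)
    p = np.tile(p, n_cycles)
    return Isotherm(a, p, cycle.temperature, cycle.compression.subphase,
                    dict(cycle.compression.metadata))


@dataclass
class MapParams:
    """Ground truth of one synthetic diffraction map.

    ``peaks`` are ``(qxy, qz, fwhm_xy, fwhm_z, amplitude)`` tuples in
    Å⁻¹/counts; amplitude is the peak height at the maximum.
    """

    peaks: list[tuple[float, float, float, float, float]] = field(
        default_factory=lambda: [(1.458, 0.0, 0.0103, 0.30, 600.0),
                                 (1.346, 0.681, 0.0235, 0.30, 200.0)]
    )
    qxy_range: tuple[float, float, float] = (1.1, 1.7, 0.002)  # start, stop, step
    qz_range: tuple[float, float, float] = (0.0, 0.9, 0.01)
    background: float = 20.0
    poisson: bool = False
    wavelength: float = 1.55
    resolution: float = 0.005
    seed: int = 0


#: presets mirroring the studied condensed phases (peak geometry only)
MAP_PRESETS = {
    # two-peak centered-rectangular pattern, tilted chains
    "dppc_water": [(1.344, 0.693, 2 / 82, 0.30, 250.0), (1.458, 0.0, 2 / 382, 0.30, 600.0)],
    "dppc_ptx_epi": [(1.346, 0.681, 2 / 85, 0.30, 220.0), (1.458, 0.0, 2 / 195, 0.30, 550.0)],
    # single-peak hexagonal, untilted
    "dmps_water": [(1.489, 0.0, 2 / 382, 0.30, 700.0)],
    "dmps_ptx_epi": [(1.487, 0.0, 2 / 370, 0.30, 650.0)],
}


def gen_map(p: MapParams) -> GIXDMap:
    """Synthesise an intensity map from :class:`MapParams`."""
    qxy = np.arange(*p.qxy_range)
    qz = np.arange(*p.qz_range)
    qxy_g, qz_g = np.meshgrid(qxy, qz)
    intensity = np.full(qxy_g.shape, float(p.background))
    for cx, cz, wxy, wz, amp in p.peaks:
        lor = (wxy / 2) ** 2 / ((qxy_g - cx) ** 2 + (wxy / 2) ** 2)
        sig_z = wz / (2 * math.sqrt(2 * math.log(2)))
        gau = np.exp(-0.5 * ((qz_g - cz) / sig_z) ** 2)
        intensity += amp * lor * gau
    if p.poisson:
        rng = np.random.default_rng(p.seed)
        intensity = rng.poisson(intensity).astype(float)
    return GIXDMap(
        qxy=qxy,
        qz=qz,
        intensity=intensity,
        wavelength=p.wavelength,
        resolution=p.resolution,
        metadata={"ground_truth": asdict(p)},
    )


@dataclass
class FrameParams:
    """Ground truth of synthetic monolayer frames.

    The lipid leaflet (counts per type, default 80/80/40 as in the
    reference ternary membrane) sits on a jittered square lattice with
    chains drawn from the programmed tilt distribution.  Optional drug
    molecules are placed as clusters of known size and spacing; optional
    donor/acceptor probes realise an exactly countable hydrogen-bond
    set.
    """

    box: tuple[float, float, float] = (8.0, 8.0, 25.5)  # nm
    lipid_counts: dict[str, int] = field(
        default_factory=lambda: {"DPPC": 80, "CHOL": 80, "DMPS": 40}
    )
    n_carbons: int = 8
    cc_bond: float = 0.127     # nm, carbon spacing along the chain
    ch_bond: float = 0.109     # nm
    head_z: float = 10.0       # nm, headgroup plane
    tilt_deg: float = 0.0      # mean chain tilt from z
    tilt_distribution: str = "delta"   # "delta" | "isotropic"
    jitter: float = 0.02       # nm, in-plane lattice jitter
    drug_counts: dict[str, int] = field(default_factory=dict)
    cluster_size: int = 1
    cluster_spacing: float = 0.45      # nm
    drug_z: dict[str, float] = field(default_factory=dict)
    n_hbonds: int = 0
    n_decoy_pairs: int = 0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.lipid_counts.values()):
            raise ValueError("lipid counts must be positive")
        if self.cluster_size < 1:
            raise ValueError("cluster size must be >= 1")
        if self.tilt_distribution not in ("delta", "isotropic"):
            raise ValueError("tilt_distribution must be 'delta' or 'isotropic'")


def _lattice_sites(n: int, lx: float, ly: float, margin: float = 0.3) -> np.ndarray:
    # refuse placements denser than one molecule per (0.3 nm)² of leaflet
    if n > lx * ly / 0.09:
        raise ValueError(f"overfilled box: {n} molecules in {lx}x{ly} nm")
    cols = math.ceil(math.sqrt(n * lx / ly))
    rows = math.ceil(n / cols)
    xs = np.linspace(margin, lx - margin, cols)
    ys = np.linspace(margin, ly - margin, rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])[:n]


def _chain_direction(rng: np.random.Generator, p: FrameParams) -> np.ndarray:
    if p.tilt_distribution == "isotropic":
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    tau = math.radians(p.tilt_deg)
    phi = rng.uniform(0, 2 * math.pi)
    return np.array([math.sin(tau) * math.cos(phi), math.sin(tau) * math.sin(phi), math.cos(tau)])


def _perpendicular(u: np.ndarray, alpha: float) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return math.cos(alpha) * e1 + math.sin(alpha) * e2


def _one_frame(p: FrameParams, rng: np.random.Generator) -> Frame:
    lx, ly, lz = p.box
    positions, names, mol_ids, mol_types = [], [], [], []
    mid = 0

    def add_atom(pos, name):
        positions.append(np.asarray(pos, dtype=float))
        names.append(name)
        mol_ids.append(mid)
        mol_types.append(current_type)

    n_lipids = sum(p.lipid_counts.values())
    sites = _lattice_sites(n_lipids, lx, ly)
    sites = sites + rng.normal(0.0, p.jitter, sites.shape)
    order = []
    for t, c in p.lipid_counts.items():
        order.extend([t] * c)
    for (x, y), current_type in zip(sites, order):
        head = np.array([x % lx, y % ly, p.head_z])
        add_atom(head, "P0")
        u = _chain_direction(rng, p)
        for k in range(1, p.n_carbons + 1):
            c_pos = head + k * p.cc_bond * u
            add_atom(c_pos, f"C{k}")
            alpha = rng.uniform(0, 2 * math.pi)
            v = _perpendicular(u, alpha)
            add_atom(c_pos + p.ch_bond * v, f"H{k}a")
            add_atom(c_pos - p.ch_bond * v, f"H{k}b")
        mid += 1

    # drugs: cluster centers on a coarse grid, members in a polygon of
    # side cluster_spacing so nearest-neighbour distances are exact
    for drug, count in p.drug_counts.items():
        current_type = drug
        n_clusters = math.ceil(count / p.cluster_size)
        centers = _lattice_sites(n_clusters, lx, ly, margin=1.0)
        centers = centers + rng.uniform(-0.1, 0.1, centers.shape)
        z = p.drug_z.get(drug, p.head_z + 1.0)
        placed = 0
        for cx, cy in centers:
            k = min(p.cluster_size, count - placed)
            if k <= 0:
                break
            if k == 1:
                offsets = [np.zeros(2)]
            else:
                # regular polygon with side length = cluster_spacing
                rad = p.cluster_spacing / (2 * math.sin(math.pi / k))
                theta0 = rng.uniform(0, 2 * math.pi)
                offsets = [
                    rad * np.array([math.cos(theta0 + 2 * math.pi * j / k),
                                    math.sin(theta0 + 2 * math.pi * j / k)])
                    for j in range(k)
                ]
            for off in offsets:
                add_atom([(cx + off[0]) % lx, (cy + off[1]) % ly, z], "C1")
                mid += 1
                placed += 1

    # hydrogen-bond probes: n_hbonds bonded triples (OD–HD···OA) at
    # 0.30 nm with a collinear hydrogen, plus decoys beyond any cutoff
    current_type = "HBPROBE"
    if p.n_hbonds or p.n_decoy_pairs:
        total = p.n_hbonds + p.n_decoy_pairs
        spots = _lattice_sites(total, lx, ly, margin=0.8)
        z = p.head_z - 1.5
        for i, (x, y) in enumerate(spots):
            d_pos = np.array([x, y, z])
            if i < p.n_hbonds:
                a_pos = d_pos + np.array([0.30, 0.0, 0.0])
                h_pos = d_pos + np.array([0.10, 0.0, 0.0])
            else:
                a_pos = d_pos + np.array([0.45, 0.0, 0.0])   # distance fails
                h_pos = d_pos + np.array([0.10, 0.0, 0.0])
            add_atom(d_pos, "OD1")
            add_atom(h_pos, "HD1")
            mid += 1
            current_type = "HBPROBE"
            add_atom(a_pos, "OA1")
            mid += 1

    frame = Frame(
        positions=np.array(positions),
        box=np.array([lx, ly, lz]),
        mol_ids=np.array(mol_ids),
        mol_types=np.array(mol_types, dtype=object),
        atom_names=np.array(names, dtype=object),
        metadata={"ground_truth": asdict(p)},
    )
    return frame


def gen_frames(p: FrameParams) -> list[Frame]:
    """Synthesise ``n_frames`` monolayer frames from :class:`FrameParams`."""
    rng = np.random.default_rng(p.seed)
    return [_one_frame(p, rng) for _ in range(p.n_frames)]


@dataclass
class SpectrumParams:
    """Ground truth of an s/p polarized band-spectrum pair.

    Every band is ``(center cm⁻¹, fwhm cm⁻¹, strength)`` with its
    transition dipole perpendicular to the chain axis (CH stretches);
    band amplitudes in each polarization follow the two-phase ATR model
    at the programmed chain tilt.
    """

    bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(2920.0, 12.0, 1.0), (2850.0, 10.0, 0.6)]
    )
    chain_tilt_deg: float = 31.0
    optics: atr.OpticsConfig = field(default_factory=atr.OpticsConfig)
    grid: tuple[float, float, float] = (2700.0, 3050.0, 0.5)
    noise_sigma: float = 0.0
    seed: int = 0


def gen_polarized_pair(p: SpectrumParams) -> tuple[atr.Spectrum, atr.Spectrum]:
    """Synthesise an (s, p) polarized absorbance-spectrum pair."""
    rng = np.random.default_rng(p.seed)
    w = np.arange(*p.grid)
    ratio = atr.dichroic_ratio_from_tilt(p.chain_tilt_deg, p.optics)
    a_s = np.zeros_like(w)
    a_p = np.zeros_like(w)
    for center, fwhm, strength in p.bands:
        sig = fwhm / (2 * math.sqrt(2 * math.log(2)))
        profile = strength * np.exp(-0.5 * ((w - center) / sig) ** 2)
        a_s += profile          # s-band amplitude is the reference
        a_p += ratio * profile  # p amplitude carries the dichroism
    if p.noise_sigma > 0:
        a_s = a_s + rng.normal(0, p.noise_sigma, w.size)
        a_p = a_p + rng.normal(0, p.noise_sigma, w.size)
    meta = {"ground_truth": {**asdict(p), "optics": asdict(p.optics)}}
    spec_s = atr.Spectrum(w, a_s, polarization="s", metadata=dict(meta))
    spec_p = atr.Spectrum(w.copy(), a_p, polarization="p", metadata=dict(meta))
    return spec_s, spec_p
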