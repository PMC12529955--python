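"""Grazing-incidence X-ray diffraction (GIXD) analysis of 2D lattices.

GIXD of a condensed Langmuir monolayer yields an intensity map
I(Qxy, Qz).  In-plane Bragg peaks (intensity vs Qxy, summed over a Qz
band) locate the 2D lattice; Bragg rods (intensity vs Qz around a peak)
carry the chain tilt.  This module reduces a map to profiles, fits
Lorentzian peaks / Gaussian rods, indexes the lattice as hexagonal (one
peak) or centered rectangular (two peaks, ⟨0,2⟩ + ⟨1,1⟩), and derives

* d-spacing  d = 2π/Qxy,
* lattice constants a, b and cell area  A_uc = a·b·sin γ,
* chain tilt τ from  Qz = Qxy·tan τ·cos ψ  under the nearest-neighbour
  tilt geometry (ψ_02 = 90°, sin ψ_11 = Q_02/(2·Q_11)),
* in-plane coherence length  L_xy = 2/fwhm(Qxy).

The nearest-neighbour azimuth convention is a documented model choice:
with both printed ⟨0,2⟩/⟨1,1⟩ peak sets of the reference rectangular
phase it reproduces the published tilt to the printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import models as lm

__all__ = [
    "GIXDMap",
    "BraggPeak",
    "Lattice2D",
    "FitError",
    "q_from_angles",
    "extract_profiles",
    "fit_bragg_peaks",
    "fit_rod",
    "index_lattice",
    "tilt_angle",
    "coherence_length",
    "analyze_map",
]

#: in-plane resolution below which an fwhm is resolution-limited (Å⁻¹)
DEFAULT_RESOLUTION = 0.005

#: rod center below this value is treated as sitting on the horizon (Å⁻¹)
QZ_HORIZON = 0.05


class FitError(RuntimeError):
    """Peak fitting failed to converge or the pattern violates the model."""


@dataclass
class GIXDMap:
    """Gridded diffraction intensity I(Qxy, Qz)."""

    qxy: np.ndarray        # Å⁻¹, strictly increasing
    qz: np.ndarray         # Å⁻¹, strictly increasing
    intensity: np.ndarray  # counts, shape (len(qz), len(qxy))
    wavelength: float = 1.55          # Å
    resolution: float = DEFAULT_RESOLUTION  # Å⁻¹ in-plane
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.qxy = np.asarray(self.qxy, dtype=float)
        self.qz = np.asarray(self.qz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.qxy) <= 0) or np.any(np.diff(self.qz) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.intensity.shape != (self.qz.size, self.qxy.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.qz.size}, {self.qxy.size})"
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class BraggPeak:
    """One fitted Bragg peak: in-plane position/width plus rod position."""

    qxy: float                 # Å⁻¹
    qz: float = 0.0            # Å⁻¹ (rod maximum)
    fwhm_qxy: float = np.nan   # Å⁻¹
    fwhm_qz: float = np.nan    # Å⁻¹
    amplitude: float = np.nan  # counts
    miller: tuple[int, int] | None = None
    stderr: dict = field(default_factory=dict)


@dataclass
class Lattice2D:
    """Indexed 2D lattice with tilt and coherence metadata."""

    lattice_class: str               # "hexagonal" | "centered-rectangular"
    a: float                         # Å
    b: float                         # Å
    gamma: float                     # degrees
    d_spacings: dict                 # miller -> Å
    area_per_cell: float             # Å²
    tilt: float = np.nan             # degrees
    tilt_azimuths: dict = field(default_factory=dict)   # miller -> ψ degrees
    coherence_lengths: dict = field(default_factory=dict)  # miller -> (Å, limited?)

    def __post_init__(self) -> None:
        expected = self.a * self.b * math.sin(math.radians(self.gamma))
        if abs(self.area_per_cell - expected) > 1e-9:
            raise ValueError("area_per_cell must equal a·b·sin(gamma)")


def q_from_angles(two_theta_xy: float, alpha_f: float, wavelength: float = 1.55):
    """Scattering-vector components from detector angles (degrees, Å).

    ``Qxy = (4π/λ)·sin(2θ_xy/2)`` and ``Qz = (2π/λ)·sin(α_f)``.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    qxy = 4 * math.pi / wavelength * math.sin(math.radians(two_theta_xy) / 2)
    qz = 2 * math.pi / wavelength * math.sin(math.radians(alpha_f))
    return qxy, qz


def extract_profiles(
    gmap: GIXDMap,
    qz_band: tuple[float, float],
    qxy_band: tuple[float, float],
):
    """Reduce a map to a Bragg profile and a Bragg rod.

    Returns ``((qxy, I_profile), (qz, I_rod))`` where the profile sums
    intensity over the Qz band and the rod sums over the Qxy band.
    """
    zsel = (gmap.qz >= qz_band[0]) & (gmap.qz <= qz_band[1])
    xsel = (gmap.qxy >= qxy_band[0]) & (gmap.qxy <= qxy_band[1])
    if not zsel.any():
        raise ValueError(f"empty Qz band {qz_band}")
    if not xsel.any():
        raise ValueError(f"empty Qxy band {qxy_band}")
    profile = gmap.intensity[zsel, :].sum(axis=0)
    rod = gmap.intensity[:, xsel].sum(axis=1)
    return (gmap.qxy.copy(), profile), (gmap.qz.copy(), rod)


def _initial_centers(x: np.ndarray, y: np.ndarray, n_peaks: int) -> list[float]:
    from scipy.signal import find_peaks

    span = max(y.max() - y.min(), 1e-30)
    idx, props = find_peaks(y, prominence=0.05 * span)
    if idx.size >= n_peaks:
        best = idx[np.argsort(props["prominences"])[::-1][:n_peaks]]
        return sorted(float(x[i]) for i in best)
    # fall back to evenly spaced quantiles of the range
    return list(np.linspace(x[0], x[-1], n_peaks + 2)[1:-1])


def fit_bragg_peaks(
    qxy: np.ndarray, intensity: np.ndarray, n_peaks: int = 1
) -> list[BraggPeak]:
    """Fit 1–2 Lorentzians plus a linear background to a Bragg profile.

    Returns peaks sorted by increasing Qxy.  Raises :class:`FitError`
    when the optimiser does not converge or the fitted peaks are
    degenerate (e.g. a flat profile).
    """
    x = np.asarray(qxy, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    if x.size < 5 * n_peaks:
        raise FitError(f"profile has {x.size} points; need >= {5 * n_peaks}")
    span = y.max() - y.min()
    if span <= 0:
        raise FitError("flat profile: nothing to fit")

    centers = _initial_centers(x, y, n_peaks)
    model = lm.LinearModel(prefix="bg_")
    params = model.make_params(slope=0.0, intercept=float(y.min()))
    width0 = (x[-1] - x[0]) / 20
    for i, c in enumerate(centers):
        lz = lm.LorentzianModel(prefix=f"p{i}_")
        model = model + lz
        params.update(lz.make_params())
        params[f"p{i}_center"].set(value=c, min=x[0], max=x[-1])
        params[f"p{i}_sigma"].set(value=width0 / 2, min=(x[1] - x[0]) / 4)
        params[f"p{i}_amplitude"].set(value=span * width0, min=0)

    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(f"Lorentzian fit failed: {result.message}; redchi={result.redchi:.3g}")
    peaks = []
    for i in range(n_peaks):
        height = result.params[f"p{i}_height"].value
        if not np.isfinite(height) or height <= 0.01 * span:
            raise FitError(
                f"peak {i} vanished in fit (height {height:.3g} vs span {span:.3g})"
            )
        err = {
            name: (result.params[f"p{i}_{name}"].stderr or np.nan)
            for name in ("center", "fwhm", "amplitude")
        }
        peaks.append(
            BraggPeak(
                qxy=float(result.params[f"p{i}_center"].value),
                fwhm_qxy=float(result.params[f"p{i}_fwhm"].value),
                amplitude=float(height),
                stderr=err,
            )
        )
    return sorted(peaks, key=lambda p: p.qxy)


def fit_rod(qz: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """Fit a Gaussian to a Bragg rod, honouring the Qz ≥ 0 horizon.

    Returns ``(center, fwhm)`` in Å⁻¹; the center is constrained to be
    non-negative and may be exactly 0 for an untilted phase.
    """
    x = np.asarray(qz, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size < 5:
        raise FitError("rod needs at least 5 points")
    span = y.max() - y.min()
    if span <= 0:
        raise FitError("flat rod: nothing to fit")
    gauss = lm.GaussianModel(prefix="g_")
    model = lm.ConstantModel(prefix="bg_") + gauss
    c0 = float(x[np.argmax(y)])
    params = model.make_params(bg_c=float(y.min()))
    params["g_center"].set(value=max(c0, 0.0), min=0.0, max=float(x[-1]))
    params["g_sigma"].set(value=(x[-1] - x[0]) / 10, min=(x[1] - x[0]) / 4)
    params["g_amplitude"].set(value=span * (x[-1] - x[0]) / 10, min=0)
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(f"rod fit failed: {result.message}")
    return float(result.params["g_center"].value), float(result.params["g_fwhm"].value)


def index_lattice(peaks: list[BraggPeak], resolution: float = DEFAULT_RESOLUTION) -> Lattice2D:
    """Index 1 or 2 in-plane Bragg peaks as a 2D lattice.

    One peak ⇒ hexagonal packing: d = 2π/Qxy, a = b = 2d/√3, γ = 120°.
    Two peaks ⇒ centered rectangular (γ = 90°): the peak with its rod on
    the horizon is ⟨0,2⟩ with b = 2·(2π/Q_02); the tilted ⟨1,1⟩ peak
    gives a through 1/d_11² = 1/a² + 1/b².  Patterns with more peaks, or
    two peaks whose rods cannot be assigned, are rejected.
    """
    if len(peaks) == 0:
        raise FitError("no peaks to index")
    if len(peaks) > 2:
        raise FitError(f"{len(peaks)} peaks: only hexagonal (1) or centered-rectangular (2) supported")

    if len(peaks) == 1:
        pk = peaks[0]
        d = 2 * math.pi / pk.qxy
        a = 2 * d / math.sqrt(3)
        pk.miller = (1, 0)
        lat = Lattice2D(
            lattice_class="hexagonal",
            a=a,
            b=a,
            gamma=120.0,
            d_spacings={(1, 0): d},
            area_per_cell=a * a * math.sin(math.radians(120.0)),
        )
    else:
        on_horizon = [p for p in peaks if p.qz < QZ_HORIZON]
        off_horizon = [p for p in peaks if p.qz >= QZ_HORIZON]
        if len(on_horizon) != 1 or len(off_horizon) != 1:
            raise FitError(
                "cannot assign ⟨0,2⟩/⟨1,1⟩: need exactly one rod on the horizon "
                f"(got qz = {[round(p.qz, 3) for p in peaks]})"
            )
        p02, p11 = on_horizon[0], off_horizon[0]
        p02.miller, p11.miller = (0, 2), (1, 1)
        d02 = 2 * math.pi / p02.qxy
        d11 = 2 * math.pi / p11.qxy
        b = 2 * d02
        inv_a2 = 1.0 / d11**2 - 1.0 / b**2
        if inv_a2 <= 0:
            raise FitError("inconsistent peak positions: 1/d11² <= 1/b²")
        a = inv_a2 ** -0.5
        lat = Lattice2D(
            lattice_class="centered-rectangular",
            a=a,
            b=b,
            gamma=90.0,
            d_spacings={(0, 2): d02, (1, 1): d11},
            area_per_cell=a * b,
        )
    for pk in peaks:
        if np.isfinite(pk.fwhm_qxy):
            lat.coherence_lengths[pk.miller] = coherence_length(pk.fwhm_qxy, resolution)
    return lat


def tilt_angle(lattice: Lattice2D, peaks: list[BraggPeak]) -> float:
    """Chain tilt τ (degrees) from rod maxima via Qz = Qxy·tan τ·cos ψ.

    Hexagonal phase with the rod on the horizon is untilted (τ = 0).
    For the centered-rectangular phase the nearest-neighbour tilt model
    fixes the azimuths: ψ_02 = 90° (so Qz_02 = 0 is required) and
    sin ψ_11 = Q_02/(2·Q_11).
    """
    if lattice.lattice_class == "hexagonal":
        (pk,) = peaks
        if pk.qz >= QZ_HORIZON:
            raise FitError(
                f"hexagonal peak with rod at Qz={pk.qz:.3f} is inconsistent with an untilted phase"
            )
        lattice.tilt = 0.0
        return 0.0

    p02 = next(p for p in peaks if p.miller == (0, 2))
    p11 = next(p for p in peaks if p.miller == (1, 1))
    if p02.qz >= QZ_HORIZON:
        raise FitError(
            f"⟨0,2⟩ rod at Qz={p02.qz:.3f} violates the nearest-neighbour tilt model"
        )
    sin_psi = p02.qxy / (2 * p11.qxy)
    if not 0 < sin_psi < 1:
        raise FitError(f"invalid tilt azimuth: sin(psi) = {sin_psi:.3f}")
    psi = math.asin(sin_psi)
    tau = math.atan2(p11.qz, p11.qxy * math.cos(psi))
    lattice.tilt = math.degrees(tau)
    lattice.tilt_azimuths = {(0, 2): 90.0, (1, 1): math.degrees(psi)}
    return lattice.tilt


def coherence_length(
    fwhm: float, resolution: float = DEFAULT_RESOLUTION
) -> tuple[float, bool]:
    """In-plane coherence length L = 2/fwhm (Å) with a resolution flag.

    The flag is set when the fitted width is at or below the instrument's
    in-plane resolution, i.e. the length is a lower bound.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    return 2.0 / fwhm, fwhm <= resolution


def analyze_map(
    gmap: GIXDMap,
    n_peaks: int,
    qz_band: tuple[float, float] | None = None,
    rod_halfwidth: float = 0.03,
) -> Lattice2D:
    """Full reduction of one map: profile → peaks → rods → indexed lattice.

    ``qz_band`` defaults to the whole Qz axis for the in-plane profile;
    each peak's rod is extracted within ±``rod_halfwidth`` of its fitted
    in-plane position.
    """
    if qz_band is None:
        qz_band = (float(gmap.qz[0]), float(gmap.qz[-1]))
    (qxy, profile), _ = extract_profiles(
        gmap, qz_band, (float(gmap.qxy[0]), float(gmap.qxy[-1]))
    )
    peaks = fit_bragg_peaks(qxy, profile, n_peaks)
    for pk in peaks:
        _, (qz, rod) = extract_profiles(
            gmap, qz_band, (pk.qxy - rod_halfwidth, pk.qxy + rod_halfwidth)
        )
        pk.qz, pk.fwhm_qz = fit_rod(qz, rod)
    lattice = index_lattice(peaks, gmap.resolution)
    tilt_angle(lattice, peaks)
    return lattice
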