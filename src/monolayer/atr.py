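"""Polarized ATR-IR analysis: absorbance, band detection, chain tilt.

Attenuated-total-reflectance spectra of a supported membrane are
recorded as intensity ratios, ``A = log10(I_ref/I_sample)``.  With s-
and p-polarized beams the dichroic ratio of a vibrational band reports
the orientation of its transition dipole.  The optical model used here
is the two-phase thick-film approximation for internal reflection at a
crystal/film interface (Harrick field amplitudes):

    Ex = 2·cosθ·√(sin²θ − n²₂₁) / √((1−n²₂₁)·((1+n²₂₁)·sin²θ − n²₂₁))
    Ey = 2·cosθ / √(1 − n²₂₁)
    Ez = 2·sinθ·cosθ / √((1−n²₂₁)·((1+n²₂₁)·sin²θ − n²₂₁))

with θ the internal incidence angle and n₂₁ = n_film/n_crystal.  For a
uniaxial film whose transition dipoles make an average angle θ_dip with
the surface normal,

    R = A_p/A_s = (Ex² + 2·Ez²·⟨cos²θ_dip⟩/(1−⟨cos²θ_dip⟩)) / Ey²,

which is inverted for the dipole order parameter
S_dip = (3⟨cos²θ_dip⟩−1)/2.  CH-stretch dipoles lie perpendicular to
the chain axis, so the chain order parameter is S_chain = −2·S_dip and
the mean chain tilt is ``τ = arccos √((2·S_chain+1)/3)``.  An isotropic
film gives the magic angle 54.74°; tilts beyond it indicate an
effectively random orientation and are flagged, not clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "BandFit",
    "OpticsConfig",
    "TiltResult",
    "MAGIC_ANGLE",
    "absorbance",
    "detect_bands",
    "band_shift_report",
    "field_amplitudes",
    "dichroic_ratio_from_tilt",
    "chain_tilt",
]

#: arccos(1/√3): mean dipole/chain angle of a fully random film, degrees
MAGIC_ANGLE = math.degrees(math.acos(1 / math.sqrt(3)))


class ModelViolationError(ValueError):
    """The measured dichroism is outside the uniaxial model's range."""


@dataclass
class Spectrum:
    """One IR spectrum: wavenumber grid with absorbance (or intensity)."""

    wavenumber: np.ndarray   # cm⁻¹, monotone
    absorbance: np.ndarray   # dimensionless
    polarization: str = "unpolarized"   # "s" | "p" | "unpolarized"
    stage: str = ""                     # e.g. "background", "membrane"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValueError("wavenumber and absorbance lengths differ")
        d = np.diff(self.wavenumber)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.polarization not in ("s", "p", "unpolarized"):
            raise ValueError(f"unknown polarization {self.polarization!r}")


@dataclass
class BandFit:
    """A detected vibrational band within one search window."""

    center: float         # cm⁻¹ (parabolic vertex refinement)
    area: float           # integrated absorbance above a linear baseline
    fwhm: float           # cm⁻¹
    assignment: str = ""  # e.g. "nu_as(CH2)"
    window: tuple[float, float] = (np.nan, np.nan)
    found: bool = True


def absorbance(
    intensity_sample: Spectrum, intensity_reference: Spectrum, **kwargs
) -> Spectrum:
    """A = log10(I_ref/I_sample) on a shared wavenumber grid."""
    if not np.array_equal(intensity_sample.wavenumber, intensity_reference.wavenumber):
        raise ValueError("sample and reference are on different wavenumber grids")
    i_s = intensity_sample.absorbance
    i_r = intensity_reference.absorbance
    if np.any(i_s <= 0) or np.any(i_r <= 0):
        raise ValueError("intensities must be strictly positive")
    return Spectrum(
        wavenumber=intensity_sample.wavenumber.copy(),
        absorbance=np.log10(i_r / i_s),
        polarization=kwargs.get("polarization", intensity_sample.polarization),
        stage=kwargs.get("stage", intensity_sample.stage),
    )


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    coef = np.polyfit(x - x.mean(), y, 2)
    if coef[0] >= 0:  # not concave: keep the raw maximum
        return float(x[np.argmax(y)])
    return float(-coef[1] / (2 * coef[0]) + x.mean())


def detect_bands(
    spec: Spectrum, windows: list[tuple[float, float]], assignments: list[str] | None = None
) -> list[BandFit]:
    """Locate and integrate one band per search window.

    The band center is the local maximum refined by the vertex of a
    parabola through the 5 surrounding points; the integrated area uses a
    linear baseline across the window endpoints.  Windows without an
    interior maximum yield a flagged empty entry rather than an error.
    """
    order = np.argsort(spec.wavenumber)
    w = spec.wavenumber[order]
    a = spec.absorbance[order]
    out = []
    for j, (lo, hi) in enumerate(windows):
        label = assignments[j] if assignments else f"band@{(lo + hi) / 2:.0f}"
        sel = np.nonzero((w >= lo) & (w <= hi))[0]
        if sel.size < 5:
            raise ValueError(f"window ({lo}, {hi}) covers {sel.size} points; need >= 5")
        ws, asub = w[sel], a[sel]
        imax = int(np.argmax(asub))
        baseline = asub[0] + (asub[-1] - asub[0]) * (ws - ws[0]) / (ws[-1] - ws[0])
        prominence = asub[imax] - baseline[imax]
        if imax in (0, asub.size - 1) or prominence <= 0:
            out.append(BandFit(np.nan, 0.0, np.nan, label, (lo, hi), found=False))
            continue
        k0 = max(imax - 2, 0)
        k1 = min(imax + 3, asub.size)
        center = _parabolic_vertex(ws[k0:k1], asub[k0:k1])
        corrected = asub - baseline
        area = float(np.trapezoid(corrected, ws))
        # fwhm from half-prominence crossings around the maximum
        half = prominence / 2
        left = imax
        while left > 0 and corrected[left] > half:
            left -= 1
        right = imax
        while right < corrected.size - 1 and corrected[right] > half:
            right += 1
        fwhm = float(ws[right] - ws[left])
        out.append(BandFit(center, area, fwhm, label, (lo, hi)))
    return out


def band_shift_report(before: list[BandFit], after: list[BandFit]) -> dict[str, float]:
    """Per-band center shift Δν̃ = center_after − center_before (cm⁻¹).

    Bands are matched by assignment label; positive means a shift toward
    higher wavenumbers.
    """
    after_by_label = {b.assignment: b for b in after if b.found}
    shifts = {}
    for b in before:
        if not b.found:
            continue
        if b.assignment not in after_by_label:
            raise ValueError(f"band {b.assignment!r} missing in the 'after' fit")
        shifts[b.assignment] = float(after_by_label[b.assignment].center - b.center)
    return shifts


@dataclass
class OpticsConfig:
    """ATR optical constants for the two-phase thick-film model."""

    incidence_deg: float = 45.0   # internal angle of incidence
    n_crystal: float = 3.42       # silicon
    n_film: float = 1.45          # organic film / effective rare medium

    def __post_init__(self) -> None:
        n21 = self.n_film / self.n_crystal
        theta = math.radians(self.incidence_deg)
        if math.sin(theta) ** 2 <= n21**2:
            raise ValueError(
                "no total internal reflection: sin²θ must exceed (n_film/n_crystal)²"
            )


def field_amplitudes(optics: OpticsConfig) -> tuple[float, float, float]:
    """Relative evanescent field amplitudes (Ex, Ey, Ez) at the interface."""
    theta = math.radians(optics.incidence_deg)
    n2 = (optics.n_film / optics.n_crystal) ** 2
    s2 = math.sin(theta) ** 2
    c = math.cos(theta)
    denom = math.sqrt((1 - n2) * ((1 + n2) * s2 - n2))
    ex = 2 * c * math.sqrt(s2 - n2) / denom
    ey = 2 * c / math.sqrt(1 - n2)
    ez = 2 * math.sin(theta) * c / denom
    return ex, ey, ez


@dataclass
class TiltResult:
    """Chain-tilt estimate from one polarized band pair."""

    dichroic_ratio: float     # R = A_p/A_s
    s_dipole: float           # order parameter of the transition dipole
    s_chain: float            # chain-axis order parameter (= −2·S_dip for CH dipoles)
    tilt_deg: float           # mean chain tilt from the surface normal
    optics: OpticsConfig
    beyond_magic_angle: bool = False
    note: str = ""


def dichroic_ratio_from_tilt(tilt_deg: float, optics: OpticsConfig) -> float:
    """Forward model: R = A_p/A_s of a CH-stretch band at a given chain tilt.

    Shared with the synthetic spectrum generator so that analysis and
    generation use the identical optical model.
    """
    s_chain = (3 * math.cos(math.radians(tilt_deg)) ** 2 - 1) / 2
    s_dip = -s_chain / 2
    cos2 = (2 * s_dip + 1) / 3  # ⟨cos²θ_dip⟩
    ex, ey, ez = field_amplitudes(optics)
    mx2 = (1 - cos2) / 2
    return (ex**2 * mx2 + ez**2 * cos2) / (ey**2 * mx2)


def chain_tilt(
    spec_p: Spectrum,
    spec_s: Spectrum,
    band_window: tuple[float, float],
    optics: OpticsConfig | None = None,
) -> TiltResult:
    """Mean hydrocarbon-chain tilt from an s/p polarized band pair.

    The band in ``band_window`` is integrated in both polarizations; the
    dichroic ratio is inverted through the uniaxial two-phase model for
    the dipole order parameter, converted to the chain order parameter
    (CH-stretch dipoles ⊥ chain) and finally to a mean tilt.  Ratios
    that imply an order parameter outside [−0.5, 1] raise
    :class:`ModelViolationError` instead of being clipped.
    """
    optics = optics or OpticsConfig()
    if spec_p.polarization != "p" or spec_s.polarization != "s":
        raise ValueError("pass the p-polarized spectrum first, s second")
    band_p = detect_bands(spec_p, [band_window])[0]
    band_s = detect_bands(spec_s, [band_window])[0]
    if not band_s.found or band_s.area <= 0:
        raise ValueError("no band found in the s-polarized spectrum")
    if not band_p.found:
        raise ValueError("no band found in the p-polarized spectrum")
    r = band_p.area / band_s.area

    ex, ey, ez = field_amplitudes(optics)
    # R·Ey²·(1−c)/2 = Ex²·(1−c)/2 + Ez²·c  with c = ⟨cos²θ_dip⟩
    k = (r * ey**2 - ex**2) / (2 * ez**2)
    if k < 0:
        raise ModelViolationError(
            f"dichroic ratio {r:.3f} below the model's minimum for these optics"
        )
    cos2 = k / (1 + k)
    s_dip = (3 * cos2 - 1) / 2
    s_chain = -2 * s_dip
    if not -0.5 - 1e-9 <= s_chain <= 1 + 1e-9:
        raise ModelViolationError(f"chain order parameter {s_chain:.3f} outside [-0.5, 1]")
    s_chain = float(np.clip(s_chain, -0.5, 1.0))
    tilt = math.degrees(math.acos(math.sqrt((2 * s_chain + 1) / 3)))
    beyond = tilt > MAGIC_ANGLE + 1e-9
    return TiltResult(
        dichroic_ratio=float(r),
        s_dipole=float(s_dip),
        s_chain=s_chain,
        tilt_deg=float(tilt),
        optics=optics,
        beyond_magic_angle=beyond,
        note=">magic angle: orientation effectively random" if beyond else "",
    )
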