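# Methods

This note documents the models behind each analysis module, the
defaults and why they were chosen, what the synthetic-data generators
emulate, and the known limitations.

## Isotherm analysis

A compression branch is a sequence of (A, π) pairs with A in
Å²/molecule and π in mN/m, recorded at a nominal temperature (default
294 K). `clean_branch` merges duplicate-area rows (mean pressure) and
sorts by decreasing area; downstream operations require the resulting
monotone branch.

**Compression modulus.** `Cs⁻¹ = −A·(dπ/dA)` is evaluated with a local
least-squares quadratic over an odd window (default 11 points), i.e. a
Savitzky–Golay-style derivative on a possibly non-uniform area grid.
Raw finite differences amplify trough noise (±0.1 mN/m) far beyond the
usable range; the window is configurable and is shrunk automatically
for short traces. On the exact hyperbola πA = const the estimator
reproduces the analytic identity Cs⁻¹ = π to better than 1% at
realistic sampling, which bounds the method bias.

**Phase classification.** Modulus ranges map to 2D phases: gas
[0, 12.5), liquid-expanded [12.5, 100), liquid-condensed [100, 250],
solid (250, ∞) mN/m. Values on a boundary are assigned to the higher
phase at 12.5 and 100; 250 itself stays LC, matching the usual
">250 = solid" convention.

**Lift-off and interpolated areas.** Lift-off is the largest area at
which π first exceeds a threshold (default 0.5 mN/m, five times typical
instrument noise), linearly interpolated. `area_at_pressure`
interpolates A(π) at the first crossing met on compression; inside an
LE–LC coexistence plateau the same pressure can be crossed repeatedly,
so the result carries an `ambiguous` flag rather than silently choosing.

## Mixing and synergy

Ideal-mixing area `A_id = Σ A_i·X_i` and excess area
`A_exc = A_mix − A_id` follow the standard additivity analysis of mixed
monolayers; a negative excess area indicates net attractive
interactions between components.

For subphase-dissolved drugs the per-drug area shift at pressure π is
`ΔA_drug(π) = A_drug(π) − A_water(π)`, evaluated on compression
branches only. Synergy of a drug pair is declared at a pressure when

    margin = ΔA_mix − (ΔA_a + ΔA_b) > k·σ,   σ = √(σ_a² + σ_b² + σ_mix²)

The experimental criterion in the literature is stated without a
significance rule, so the k·σ threshold (default k = 1, quadrature
propagation of the reported per-condition standard deviations) is this
package's convention and is recorded in the result metadata. A
false-positive control over additive synthetic triplets shows a flag
rate ≤ 5% at k = 2.

## Hysteresis thermodynamics

Per branch, `ΔG = N_A ∫ A dπ` over [π_low, π_high] (defaults 1 and
30 mN/m) with the trapezoid rule; the rule's error is negligible
relative to trace noise. The unit conversion is literal:
1 mN/m·Å²/molecule × N_A = 6.02214 J/mol, i.e. 1.43933×10⁻³ kcal/mol.

`ΔG_hys = ΔG_exp − ΔG_comp` is ≤ 0 whenever the expansion branch runs
at smaller areas. The hysteresis entropy sums
`R·ln(A_exp(π)/A_comp(π))` over a fixed pressure grid; the grid is an
explicit parameter (default 1 mN/m steps from 1 to 30, i.e. 30 terms)
because the sum's magnitude scales directly with grid density and no
canonical grid exists. `ΔH_hys = ΔG_hys + T·ΔS_hys` with T = 294 K by
default. Internal identities (ΔG_hys = ΔG_exp − ΔG_comp and
ΔH = ΔG + TΔS) are enforced to 1×10⁻⁹ on every record.

A caveat on absolute branch energies: published per-cycle free energies
of ternary lipid monolayers are substantially smaller than a literal
`N_A ∫ A dπ` of typical molecular areas over 1–30 mN/m, suggesting an
additional normalisation in some reports. The literal formula is
implemented; only differences and sums of branch energies — which do
not depend on that convention — are compared against published numbers.

## GIXD lattice analysis

Detector angles convert to scattering-vector components as
`Qxy = (4π/λ)·sin(2θ_xy/2)`, `Qz = (2π/λ)·sin(α_f)` (λ default
1.55 Å). A map is reduced to a Bragg profile (intensity vs Qxy summed
over a Qz band) and per-peak Bragg rods (intensity vs Qz summed over
±0.03 Å⁻¹ around each fitted peak).

In-plane peaks are fitted as Lorentzians plus a linear background —
the conventional shape for 2D powder Bragg profiles — and rods as
Gaussians with the center constrained to Qz ≥ 0 (the horizon).
Initial centers come from prominence-ranked local maxima.

Indexing: one in-plane peak ⇒ hexagonal rotator packing
(d = 2π/Qxy, a = 2d/√3, γ = 120°, one chain per cell); two peaks ⇒
centered-rectangular cell (γ = 90°, two chains), with the rod-on-horizon
peak assigned ⟨0,2⟩ (b = 2·d_02) and the tilted peak ⟨1,1⟩
(1/d_11² = 1/a² + 1/b²). Ambiguous rod patterns (both rods on or both
off the horizon) are rejected rather than guessed. `A_uc = a·b·sin γ`
is an enforced identity.

**Tilt.** `Qz = Qxy·tan τ·cos ψ` needs the tilt azimuth ψ, which the
peak positions alone do not fix. The nearest-neighbour tilt geometry is
adopted: chains tilt toward a nearest neighbour, so ψ_02 = 90° (hence
Qz_02 = 0 is required, and deviations raise a model-violation error)
and sin ψ_11 = Q_02/(2·Q_11). This choice reproduces both published
tilt values of the reference rectangular phase from their printed peak
positions (31.0°, and 31.5° vs a printed 31.6° that was evidently
computed from unrounded maxima), which is the strongest available
verification.

**Coherence length.** `L_xy = 2/fwhm(Qxy)`. Fitted widths are not
deconvolved from the instrument resolution (≈0.005 Å⁻¹ in-plane);
widths at or below the resolution flag the length as a lower bound
instead.

One published hexagonal-row unit-cell area (48.98 Å²) is inconsistent
with its own printed lattice constants (5.57·8.62 = 48.01 Å²),
presumably a transcription slip; the self-consistent drug-subphase row
is used for verification instead.

## Polarized ATR and chain tilt

Absorbance is `A = log10(I_ref/I_sample)` per point on a shared
wavenumber grid. Band detection refines the in-window maximum with a
parabolic vertex through 5 points and integrates above a linear
baseline across the window endpoints; windows without an interior
maximum return a flagged empty fit.

The chain-tilt model is the two-phase (crystal/rare-medium) thick-film
approximation for internal reflection, with Harrick's relative field
amplitudes Ex, Ey, Ez at the interface. Optical constants live in
`OpticsConfig`: incidence angle 45°, n_crystal = 3.42 (silicon),
n_film = 1.45 — all configurable, since published variants of the
dichroic analysis differ in these constants and in whether a
three-phase model is used. For a uniaxial distribution of transition
dipoles at mean angle θ_dip from the normal,

    R = A_p/A_s = (Ex² + 2·Ez²·⟨cos²θ_dip⟩/(1 − ⟨cos²θ_dip⟩)) / Ey²,

inverted for the dipole order parameter S_dip. CH-stretch dipoles are
perpendicular to the chain axis, so S_chain = −2·S_dip and the mean
tilt is τ = arccos √((2·S_chain + 1)/3). An isotropic film returns the
magic angle (54.74°); recovered tilts beyond it are flagged as
"orientation effectively random" rather than clipped, and dichroic
ratios outside the model's admissible range raise a model-violation
error.

Because the same forward model generates the synthetic polarized
spectra, round-trip tests verify the inversion, not the particular
optical constants; on real data a different published constant set
would shift recovered angles by a model-dependent offset. Polarization
naming maps 0° → p and 90° → s; a swap is a matter of relabelling the
inputs.

## Frame descriptors

Frames carry positions (nm), a periodic box, and per-particle
molecule id/type and atom names. Minimal-image periodicity applies in
x and y; z is non-periodic by default (monolayer slab geometry) with an
opt-in flag. Atom-name conventions encode annotations: `C<k>`/`H<k>a,b`
are chain carbon–hydrogen pairs, `OD<i>`/`HD<i>` donor pairs, `OA<i>`
acceptors; a donor hydrogen without its heavy atom is an annotation
error.

* **2D RDF** between molecular centers of mass, normalised per frame by
  the ideal annulus count `N_ref·ρ_target·π(r₂² − r₁²)` with the self
  particle excluded for identical selections; equals a brute-force pair
  loop exactly on the same bins.
* **H-bonds**: donor–acceptor distance < 0.35 nm and
  hydrogen–donor–acceptor angle < 30° by default (the convention of the
  widely used trajectory tools); the donor–H–acceptor
  deviation-from-linearity reading is available via
  `convention="dha"` because the phrase "H-bond angle" is ambiguous in
  much of the literature.
* **Order parameter** `S_CH(k) = ⟨(3cos²θ − 1)/2⟩` per carbon over all
  C–H vectors vs z. Sign convention: an all-trans chain along the
  normal gives −0.5. Output includes the magnitude column as well,
  since some reports plot |S|.
* **Density profile**: mass histogram along z in kg/m³, bins spanning
  [0, Lz]; summed back over slabs it reproduces the species mass
  exactly.

## Synthetic data

Generators define the study conditions and embed their full parameter
set in the output metadata.

* **Isotherms** are phenomenological, not an equation of state: the
  slope magnitude |dπ/dA| is a logistic blend of three segment slopes
  (expanded 2, plateau 0.05, condensed 8 mN/m per Å², blend width
  0.4 Å²), integrated downward from the lift-off area (default 70 Å²;
  the drug-shifted scenario uses 130 Å²), with plateau pressure 10
  (drug-shifted 30) mN/m, plateau width 10 Å², collapse at 55 mN/m and
  optional Gaussian pressure noise. Drug effects enter as area offsets,
  constant or interpolated per pressure.
* **Cycles** scale the compression branch by an area ratio r(π) ≤ 1;
  given a target TΔS_hys the constant ratio is solved in closed form
  from the entropy-grid formula, making recovery tests exact inversions.
* **Maps** are sums of Lorentzian(Qxy)×Gaussian(Qz) peaks over a flat
  background (20 counts) with optional Poisson noise; presets encode the
  published peak geometries of the studied condensed phases.
* **Frames** place 80/80/40 lipids (ternary 4:4:2 leaflet) on a
  jittered square lattice in an 8×8×25.5 nm box; chains are 8-carbon
  abstractions with two hydrogens per carbon, drawn from a delta-tilt
  (uniform azimuth) or isotropic orientation distribution. Drugs are
  single-site molecules placed in clusters with exact nearest-neighbour
  spacing; hydrogen-bond probes are collinear O–H···O triples at 0.30 nm
  plus decoys at 0.45 nm, so programmed counts are exact.
* **Polarized spectra** are Gaussian bands whose p/s amplitude ratio
  comes from the same ATR forward model the analysis inverts.

What passing the synthetic suites does **not** show: real trough data
have drift, meniscus artefacts and leakage that the noise model omits;
real diffraction has footprint/polarization corrections and coexisting
phases; real membranes are not uniaxial single-component films; the
frame generator has no force field, so descriptor values are geometric
constructions, not predictions of molecular organisation. Quantities
that require the original measurements or long atomistic trajectories
(absolute branch free energies, per-pair H-bond averages of specific
chemistries) are exercised structurally, not numerically.

## Numerical choices and degenerate inputs

* Differentiation window defaults to 11 points, shrunk to the trace
  length when necessary; fewer than 5 points is an error.
* Peak fits raise on non-convergence, flat profiles, and peaks that
  collapse into the background; they never return silent defaults.
* Interpolations refuse targets outside the data range, naming the
  offending trace.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is bit-reproducible under a fixed seed.
* Problem sizes in the test suite (≤ 80-particle oracle fixtures,
  50-seed recovery sweeps, ≤ 320-molecule frames) were chosen so the
  statistical assertions have comfortable margins while the whole suite
  runs in well under a minute.
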