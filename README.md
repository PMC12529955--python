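# monolayer

Quantitative analysis of drug–membrane interactions in Langmuir
monolayers and their companion molecular models.

Model biological membranes spread at the air–water interface (e.g. a
DPPC:cholesterol:DMPS 4:4:2 "cancer-membrane" leaflet) are a standard
platform for asking how anticancer drugs — individually or
co-administered — incorporate into, condense, fluidise or disrupt a
lipid film. The raw observables are π–A isotherms, compression–expansion
cycles, grazing-incidence X-ray diffraction (GIXD) maps, polarized
ATR-IR spectra and simulation configuration frames. This package turns
each of those into the derived quantities practitioners actually
compare:

* **Isotherms** — compression modulus `Cs⁻¹ = −A(dπ/dA)`, 2D phase
  classification (G/LE/LC/S), lift-off area, interpolated area at a
  target pressure.
* **Mixing & synergy** — ideal area `A_id = Σ AᵢXᵢ`, excess area,
  per-drug area shifts `ΔA(π) = A_drug − A_water`, and the two-drug
  synergy criterion `ΔA_mix > ΔA_a + ΔA_b` with propagated
  uncertainties.
* **Hysteresis thermodynamics** — `ΔG = N_A ∫ A dπ` per branch,
  `ΔG_hys = ΔG_exp − ΔG_comp`, `ΔS_hys = Σ_π R ln(A_exp/A_comp)`,
  `ΔH_hys = ΔG_hys + TΔS_hys` (kcal/mol).
* **GIXD** — Lorentzian Bragg-peak / Gaussian Bragg-rod fitting,
  hexagonal or centered-rectangular indexing (`d = 2π/Qxy`), chain tilt
  from `Qz = Qxy tan τ cos ψ` under nearest-neighbour tilt geometry,
  unit-cell area `A_uc = a·b·sin γ`, coherence length `L_xy = 2/fwhm`.
* **Polarized ATR** — `A = log10(I₀/I₁)`, band detection and shift
  reports, and mean chain tilt from the s/p dichroic ratio through a
  two-phase thick-film optical model.
* **Frame descriptors** — in-plane 2D RDF, geometric H-bond counting
  (0.35 nm / 30° criterion), per-carbon order parameter
  `S_CH = ⟨(3cos²θ−1)/2⟩`, z-density profiles.
* **Synthetic data** — seeded generators for every input class with
  embedded ground truth, so the full pipeline is testable end to end.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Index the condensed DPPC phase formed on a subphase containing the
paclitaxel + epirubicin mixture, straight from its two Bragg-peak
maxima (⟨0,2⟩ at Qxy = 1.458 Å⁻¹ on the horizon, ⟨1,1⟩ at 1.346 Å⁻¹
with the rod maximum at Qz = 0.681 Å⁻¹):

```python
from monolayer.gixd import BraggPeak, index_lattice, tilt_angle

peaks = [BraggPeak(qxy=1.458, qz=0.0, fwhm_qxy=2/195),
         BraggPeak(qxy=1.346, qz=0.681, fwhm_qxy=2/85)]
lat = index_lattice(peaks)
tau = tilt_angle(lat, peaks)
print(f"a={lat.a:.2f} b={lat.b:.2f} Auc={lat.area_per_cell:.2f} tau={tau:.1f}")
```

```
a=5.55 b=8.62 Auc=47.86 tau=31.0
```

— a centered-rectangular cell of 5.55 × 8.62 Å holding two chains over
47.86 Å², with chains tilted 31.0° from the surface normal toward a
nearest neighbour.

Assess drug synergy from measured area shifts at 5 mN/m
(ΔA_PTX = 45.2 ± 1.2, ΔA_EPI = 22.0 ± 0.3, ΔA_PTX+EPI = 87.3 ± 0.4 Å²):

```python
from monolayer.mixing import AreaShiftTable, assess_synergy

table = AreaShiftTable([5.0], [45.2], [22.0], [87.3])
res = assess_synergy(table, [[1.2, 0.3, 0.4]])[0]
print(f"margin={res.margin:.1f} sigma={res.uncertainty:.2f} synergy={res.synergy}")
```

```
margin=20.1 sigma=1.30 synergy=True
```

The mixture's shift exceeds the sum of the single-drug shifts by
20.1 Å², 15 times the propagated uncertainty: synergistic
incorporation.

Hysteresis thermodynamics of a synthetic cycle programmed for
TΔS_hys = −2.35 kcal/mol:

```python
from monolayer import synthetic as syn
from monolayer.hysteresis import analyze_cycle

th = analyze_cycle(syn.gen_cycle(syn.CycleParams(target_t_ds=-2.35)))
print(f"dG_hys={th.dg_hys:.3f} TdS={th.t_ds_hys:.3f} dH={th.dh_hys:.3f}")
```

```
dG_hys=-0.304 TdS=-2.350 dH=-2.654
```

## Command line

Every analysis is also exposed as a `monolayer` subcommand:

```sh
monolayer simulate --kind isotherm --seed 1 --out trace.csv
monolayer isotherm --in trace.csv --modulus --lift-off
monolayer gixd --map map.txt --peaks 2
monolayer atr --p p.txt --s s.txt --band 2880,2960
monolayer traj rdf --frames frames.xyz --ref EPI --target EPI
monolayer hysteresis --in cycles.csv --limits 1,30 --grid 1.0
```

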