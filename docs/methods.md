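# Methods

`barriermc` computes broad-beam transmission of megavoltage photon beams
through concrete primary barriers by analog Monte Carlo transport, together
with the analytic references used to validate the engine and the fitting
tools used to condense transmission curves into tenth-value layers (TVLs)
and distance-fall-off parameters. This note records the model, the data it
rests on, the numerical choices, and the limits of what the shipped tests
demonstrate.

## Transport model

Photons are followed one interaction at a time through a homogeneous
concrete slab. Free paths are sampled from the total linear attenuation
coefficient; the interaction channel is chosen with probability
μ_process/μ_total. Compton scattering samples the exact Klein–Nishina
distribution for a free electron at rest (composition–rejection in
ε = E′/E); photoelectric absorption terminates the history; pair production
terminates the primary and emits two 0.511 MeV annihilation photons at the
interaction site, back to back along an isotropic random axis. Histories
end when the energy falls below the 10 keV cutoff, when the photon drifts
10 m or more from the beam axis, or when it re-crosses the proximal slab
face ("reflected back into the vault"). There is no charged-particle
transport (hence no bremsstrahlung buildup in the barrier), no coherent
angular deflection in the default configuration, no bound-Compton/Doppler
correction, and no variance reduction.

Geometry: the target (source) is at the origin, the beam axis along +z, the
slab occupying z ∈ [d_s − t, d_s] with d_s = 6 m by default. Sources are a
divergent square field (side quoted at the 1 m isocenter; fluence uniform
across the field), a non-divergent circular field, or a pencil beam. Disc
"detectors" sit on the axis at d_w beyond the distal face (0.3 m for the
principal detector, radius 50 cm by default, adjusted in proportion to the
field for small fields); each plane crossing scores 1/(A·|cos θ|) with
|cos θ| floored at 0.1 to bound the estimator variance. Air kerma is
accumulated as fluence × E × (μ_tr/ρ)_air per crossing. Statistical
uncertainties use the history-by-history estimator over per-history score
sums. A ring tally (15 cm wide annuli) at the principal plane records the
lateral profile.

Reproducibility: histories are processed in fixed-size batches, each batch
drawing from `SeedSequence(seed, batch_index)`. Results are bit-identical
for a fixed (seed, batch size) pair. The single-scatter validation mode
(Compton-only, at most one scatter) additionally has two specialized
kernels — a vectorized numpy one and a compiled (numba) scalar loop —
selected automatically; they implement the identical analog physics and
estimators and are cross-checked against the generic engine statistically.

## Barrier transmission definition

The transmission reported by `compute_B` is

    B = (K_a / D0) · (d / 1 m)²,

with K_a the tallied air kerma per source photon at d = d_s + d_w on the
axis and D0 the water dose per photon at d_max, 1 m, for the 10×10 cm²
reference field (shipped as per-beam constants together with the mean
energies of the 4–18 MV reference beams). Because D0 is referenced to the
10×10 cm² beam, the kerma per source photon of a simulation that fills a
larger field is rescaled by (field side at isocenter / 10 cm)²: at fixed
machine output the photon emission rate is proportional to the field solid
angle. Head-scatter variation of the output with field size is neglected.
This normalization was cross-checked against the three-TVL parameterization
of the 4 MV transmission curve: at t = 100 cm the surrogate-spectrum
pipeline reproduces the parameterized B within a few percent.

Required transmission for a design goal is B_req = P d²/(W U T).

## Interaction data

No photon cross-section library is assumed at run time; the package ships
plain-text per-element tables (10 keV–25 MeV, ~300-point log grid) built by
`scripts/build_xsec_tables.py`:

* **Incoherent**: Klein–Nishina total cross section × Z/A. Binding
  (incoherent-function) corrections are intentionally omitted so that the
  tabulated coefficient is exactly the one the transport engine samples
  from. The omission overstates incoherent scattering below ~100 keV
  (a few percent at 60 keV for mid-Z elements).
* **Coherent**: Thomson cross section modulated by a Molière
  three-exponential form factor, integrated numerically. Accuracy is tens
  of percent; it is excluded from the default total and never sampled, and
  is tabulated only for completeness and for the subtraction below.
* **Photoelectric**: anchored by subtracting the incoherent and coherent
  models from transcribed NIST-lineage total attenuation coefficients
  (H, C, N, O, Al, Si, Ca, Fe) at energies where the photoelectric share
  exceeds 3%, log-log interpolated, and continued beyond the last anchor
  with a power law whose exponent relaxes from the local slope toward the
  asymptotic 1/E. Elements without anchors (Na, Mg, S, Ar, K) interpolate
  the atomic cross section quadratically in ln Z.
* **Pair** (nuclear + electronic): anchored above 2 MeV by the same
  subtraction; below 2 MeV a (E − 2m_ec²)³ threshold shape; unanchored
  elements interpolate the cross section per Z(Z+1) linearly in ln Z. Pair
  coefficients are identically zero below 1.022 MeV.

Accuracy audit (mixture level): the concrete linear attenuation coefficient
at 6.00 and 1.33 MeV agrees with independently published values to ~0.4%;
the photoelectric/Compton crossing of concrete computes to 51.7 keV
(literature ≈ 55 keV; most of the deficit is the omitted binding
correction); the 2.6→3.3 MeV transmission contrast across 150 cm agrees to
~6%. Mixtures obey exact mass-fraction additivity; interpolation between
nodes is log-log linear.

Air kerma uses the mass energy-transfer coefficient of dry air,
μ_tr = μ_en/(1 − g) with a small approximate radiative fraction g
(<1% effect below 10 MeV). Standard dry air is embedded at
1.205 × 10⁻³ g/cm³ (20 °C). With that density the 6.3 m narrow-beam air
transmissions are 0.959 (1.33 MeV) and 0.981 (6 MeV); quoting them at an
air density of 1.0 × 10⁻³ g/cm³ would give 0.966 and 0.984.

## Beam spectra and the surrogate

Published linac spectra are user-supplied two- or three-column text files.
For self-contained tests a surrogate spectrum Φ(E) ∝ (E_max − E)·e^(−bE)
on [0.05 MeV, E_max] stands in, with b solved (Brent) so the binned mean
energy matches the reference mean of the nominal beam (1.52 MeV for 4 MV …
4.89 MeV for 18 MV); bins are 0.05 MeV wide. The surrogate captures the
gross hardness of a flattened beam but none of the machine-specific
structure (target/filter details, off-axis softening — the engine assumes
the spectrum is invariant across the field). Consequently the shipped tests
demonstrate qualitative broad-beam behaviour (initial spectral softening
with a mean-energy minimum near 50 cm, monotone transmission decrease,
field-size saturation above ~150 cm) and order-of-magnitude agreement of
absolute B — not the published per-beam TVL values, which require the true
spectra as input.

## Analytic oracles

* Pencil/narrow-beam limit: B_N = e^(−μt) (closed form).
* Single-scatter transmission for a parallel circular beam: primary
  e^(−μt) plus the double integral over scattering depth T and angle θ up
  to θ_m(T) = atan[R/(d_w + t − T)] of the Klein–Nishina-weighted,
  attenuation-corrected scatter kernel, with the scattered-photon
  coefficient μ′ evaluated at the Compton-shifted energy E′(θ). Evaluated
  by tensor Gauss–Legendre quadrature with the order doubled until two
  successive evaluations of the scatter term agree to a requested relative
  tolerance (default 10⁻⁴); both integrands are smooth (the tan θ factor
  is benign since θ_m < π/2). Consistent with the validation condition,
  the coefficients default to Compton-only values μ = ρ_e σ_KN (the full
  total is available as an option; the difference is ~10%).
* Small-angle closed form B ≈ e^(−μt){1 + π(r₀²/σ) μ t (R/d_w)²}, valid
  for d_w ≫ R and d_w ≫ t; a warning is issued outside that domain.

## Distance and field-size model

Beyond the barrier the irradiated slab re-emits scattered photons like an
extended source, so the axial air-kerma rate falls off more slowly than
inverse square from the target. The axial kernel of a finite isotropic
disc, P(d) ∝ ln{1 + [α(f + f₀)/(d − d_s)]²}, is exposed with reference
constants α = 28, f₀ = 0.02 m for thick barriers and a 2.4 m field; it is
normalized to 1 at d = d_s + d_w and approaches 1/d² for d ≫ d_s. With the
reference constants the 20 m prediction exceeds the inverse-square
extrapolation from 6.3 m by a factor ≈ 3. `fit_distance_model` performs
the weighted least-squares fit of (α, f₀) to a normalized profile.

Scaled-down Monte Carlo profiles (≤1.5 m slabs, ≤10⁷ histories) show the
far-field AKR approaching and exceeding-from-below the inverse-square
curve as the barrier thickens, and are described far better by the disc
kernel than by a point source; demonstrating the full factor-2+ excess
requires the 2–2.4 m barriers and ≥10⁸-history runs of a production study.

## TVL fitting

Curves of (t, B, σ_B) are fitted on log₁₀B with weights 1/σ_log²,
σ_log = σ_B/(B ln 10), by bounded ([5, 100] cm) nonlinear least squares
(multi-start from graphical estimates: the first-decade thickness and the
late-slope decade). Two forms are supported: the three-TVL piecewise form
(continuous at TVL₁ and TVL₁+TVL₂) and the TVL₁/TVL_e form, extended below
the first decade by 10^(−t/TVL₁). Reported uncertainties are 1 SD from the
fit covariance; the residual diagnostic is the mean of |B_fit − B_i|/B_i.
Zero-count tally points carry only a rule-of-three upper bound and are
excluded from fits. Density rescaling conserves areal density
(TVL′ = TVL·ρ_ref/ρ_actual); the companion thickness-equivalence ratio
ρ_actual/ρ_ref (0.974 for 2.29 vs 2.35 g/cm³) is exposed separately to
keep the direction unambiguous.

## Problem sizes and statistical conventions

The validation protocols shipped in `barriermc.validation` use, as the
package's standard study sizes: 10⁷ histories per thickness for the
narrow-beam slope ladders (regression weighted by Poisson counts,
zero-count points excluded), and a count-targeted schedule for the
single-scatter ladder that aims at ~10³ detector counts per point from the
quadrature prediction, capped at 8×10⁸ histories per point. Under analog
transport the deepest points (B_f ~ 10⁻⁶ with a detector/beam area ratio
of 0.137) remain count-starved at any practical cap; their relative
uncertainty (~12% at 150 cm) dominates the uncertainty of the mean
MC/oracle ratio (~2%), which is the figure the comparison quotes.

## Known limitations

* Free-electron Compton (no binding/Doppler) and no coherent deflection:
  fine above ~100 keV, increasingly approximate below.
* No electron transport: kerma, not dose, beyond the barrier; no
  bremsstrahlung regeneration (negligible for concrete at these energies).
* The embedded interaction tables are reconstructed from published totals
  plus theory, with the per-process split least certain where the
  subtraction is small (pair near threshold, photoelectric above 300 keV).
* The surrogate spectrum is a stand-in: any result that depends on the
  detailed spectral shape (absolute TVLs per nominal MV) needs
  user-supplied published spectra.
* Air attenuation between barrier and detector is ignored by default
  (2–4% effect); an optional straight-line exponential correction exists.
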