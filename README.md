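# barriermc

Monte Carlo photon transport and analysis for **linac primary-barrier
shielding in concrete**.

Radiotherapy vaults are shielded using tenth-value layers (TVLs): the
concrete thickness that attenuates the barrier transmission *B* by a factor
of ten. Reference TVL tables trace back to decades-old beam data, and
recent measurements suggest they can underpredict the air-kerma rate
outside a barrier severalfold. `barriermc` is a research-grade toolkit for
recomputing barrier transmission from first principles:

* an **analog Monte Carlo engine** for photons (10 keV–25 MeV) in a slab
  geometry — Klein–Nishina Compton scattering, photoelectric absorption,
  pair production with on-the-spot annihilation, divergent/parallel/pencil
  sources, axial disc detectors with fluence and air-kerma tallies, and
  history-by-history uncertainties;
* embedded **photon interaction data** for the standard concrete mix and
  dry air, with mixture rules and fluence-to-air-kerma conversion;
* **analytic validation oracles**: the narrow-beam exponential limit, the
  single-scatter double integral for a circular beam, and its small-angle
  closed form;
* **shielding analysis**: the mathematically consistent transmission
  definition B = (K̇_a/Ḋ₀)(d/1 m)², required-B arithmetic (P = B·WUT/d²),
  TVL₁/TVL₂/TVL₃ and TVL₁/TVL_e curve fitting with uncertainties, density
  rescaling, and the extended ("pseudo") source model for the slower-than-
  inverse-square fall-off of air kerma beyond a thick barrier.

The model, data provenance, numerical choices and limitations are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Transmission of a 6 MV-like beam (surrogate spectrum, mean 1.79 MeV,
40×40 cm² field at the isocenter) through 80 cm of standard concrete,
detector 0.3 m beyond the distal face:

```python
import barriermc as bm
from barriermc.transport import SlabGeometry, SourceConfig, TransportConfig

concrete = bm.standard_concrete()              # 2.35 g/cm^3, standard mix
spectrum = bm.make_surrogate_spectrum(6.0)     # 6 MV-like, mean 1.79 MeV
norm = bm.beam_normalization("6")              # dose per photon at 1 m

cfg = TransportConfig(
    source=SourceConfig(kind="divergent_square", spectrum=spectrum,
                        field_side_at_iso=40.0),
    slab=SlabGeometry(thickness=80.0, material=concrete),
    histories=2_000_000, rng_seed=42)
res = bm.run_transport(cfg)
b = bm.compute_B(res, norm.dose_per_photon)
```

which prints:

```
histories        : 2000000
detector counts  : 1110
kerma/photon     : 4.680e-19 Gy
B (d = 6.3 m)    : 4.575e-03 +- 1.6e-04
emergent mean E  : 1.474 MeV (incident 1.79 MeV)
```

Reading the numbers: of 2×10⁶ source photons, 1110 crossed the 50 cm
principal detector; the tallied air kerma per photon, normalized by the
per-photon reference dose and corrected to 1 m by d², gives a barrier
transmission of 4.6×10⁻³ ± 4% — one photon in ~220 of the incident kerma
survives 80 cm of concrete. The emergent beam is *softer* than the
incident one: scattered photons dominate behind a broad-beam barrier.

A thickness ladder of such runs (`sweep_thickness`) yields a transmission
curve that `fit_tvl` condenses into TVL parameters, e.g.
`fit_tvl(curve, model="three")` → TVL₁, TVL₂, TVL₃ with 1 SD errors and
the mean relative residual. For clinically realistic goals
(`required_B(ShieldingSpec(P=2e-5, W=1e3, U=0.25, T_occ=1, d=6.3))` →
`3.2e-06`) the ladder must extend to B ~ 10⁻⁶.

Published beam spectra are supplied as plain-text two-column files and
loaded with `load_spectrum`; the surrogate generator stands in for them in
the shipped tests.

## Command line

```bash
barriermc run --config cfg.yaml --out tally.json     # one simulation
barriermc sweep --config cfg.yaml --thicknesses 10:150:10 --beam 6 --out curve.csv
barriermc fit-tvl curve.csv --model three
barriermc required-b -P 2e-5 -W 1000 -U 0.25 -T 1 -d 6.3
barriermc mu --energy 6.0
barriermc oracle-single-scatter --energy 2 --radius 135 --dw 30
```

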