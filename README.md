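# memfibril

Quantitative analysis of membrane-associated amyloid fibrillation for
solid-state-NMR and biophysics labs: a Python library that turns the raw
quantitative readouts of an Aβ–membrane interaction study — 31P
relaxation series, dipolar dephasing curves, 2D spin-diffusion spectra,
dark-field TEM intensities, and plate-reader traces — into physical
parameters with propagated uncertainties.

## What it computes

- **Lipid dynamics** (`memfibril.relaxation`): fast (τ_f, ns; headgroup
  rotation/wobble) and slow (τ_s, µs; lateral diffusion) lipid motion
  correlation times from 31P T1/T2 relaxation, via the CSA-driven rate
  equations

  R1 = (2/15) ω²σ²(1+η²/3) [S²τ_s/(1+(ωτ_s)²) + (1−S²)τ_f/(1+(ωτ_f)²)],

  their analytically invertible large-(ωτ_f)² simplification, first-order
  uncertainty propagation (constants C1–C4), and peptide-induced changes
  Δτ against controls.
- **Internuclear distances** (`memfibril.dipolar`): powder-averaged
  PITHIRDs-CT (13C–13C) and REDOR (13C–31P) dephasing simulation and
  grid matching over 4–8 Å; d = (μ0/4π)γ_aγ_bħ/(2πr³).
- **Contact classification** (`memfibril.spindiff`): crosspeak volume
  integration, the isotope-dilution Reduction statistic
  (V1,d/V0,d)/(V1,n/V0,n)×100% with its four-term propagated
  uncertainty, the pair-product p² dilution expectation, and secondary
  chemical-shift deviations (ΔδCβ − ΔδCα) for β-strand calls.
- **Mass-per-length** (`memfibril.mpl`): TMV-standardized MPL
  (131 kDa/nm) from dark-field TEM intensities and a constrained
  Gaussian-mixture fit at integer multiples of a unit MPL to count
  filaments and infer rotational symmetry.
- **Assays** (`memfibril.assays`): ThT fibrillation lag periods
  (logistic fit, lag = t_half − 2/k), BCA binding percentages, MTT
  viability, GdnHCl denaturation midpoints, and t-test annotation.
- **Synthetic data** (`memfibril.synthetic`): seeded generators for every
  input above with known ground truth.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import memfibril as mf
from memfibril.synthetic import gen_relaxation_set

sets = gen_relaxation_set(tau_f=1.8e-9, tau_s=4.0e-6,
                          control_tau_f=1.5e-9, control_tau_s=4.5e-6,
                          noise_sd=0.02, seed=42)
sample = mf.invert_simplified(mf.fit_exponential_decay(sets["sample_T1"]),
                              mf.fit_exponential_decay(sets["sample_T2"]))
control = mf.invert_simplified(mf.fit_exponential_decay(sets["control_T1"]),
                               mf.fit_exponential_decay(sets["control_T2"]))
delta = mf.delta_correlation_times(sample, control, "5 h")
print(f"tau_f = {sample.tau_f*1e9:.2f} ns, tau_s = {sample.tau_s*1e6:.2f} us")
print(f"Delta tau_f = {delta.delta_tau_f*1e9:+.2f} +/- {delta.sigma_delta_f*1e9:.2f} ns")
```

prints

```
tau_f = 2.03 ns, tau_s = 3.87 us
Delta tau_f = +0.22 +/- 0.11 ns
```

i.e. the fitted relaxation times invert to a ~2 ns headgroup correlation
time and a ~4 µs diffusion correlation time, and the peptide-containing
sample shows a positive Δτ_f — restricted headgroup motion on peptide
binding — about two combined standard deviations from zero.  The
`examples/` directory holds one narrative script per capability
(`lipid_dynamics.py`, `distance_fitting.py`, `isotope_dilution.py`,
`mass_per_length.py`, `aggregation_assays.py`); each generates a small
synthetic input, runs the analysis, and prints annotated results.

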