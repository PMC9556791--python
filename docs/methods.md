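# Methods

This note documents the models implemented in `memfibril`, the
assumptions and numerical choices behind them, and what the synthetic
data generators do and do not emulate.

## 31P relaxation and lipid correlation times (`memfibril.relaxation`)

**Model.** Phosphate-headgroup 31P relaxation is driven by chemical-shift
anisotropy (CSA) reorientation under two motional timescales: a fast
component τ_f (nanoseconds; headgroup uniaxial rotation and wobble) and a
slow component τ_s (microseconds; lateral diffusion around the curved
vesicle surface), partitioned by an order parameter S:

    R1 = (2/15) ω² σ² (1 + η²/3) [ S² τ_s/(1+(ωτ_s)²) + (1−S²) τ_f/(1+(ωτ_f)²) ]
    R2 = (1/15) ω² σ² (1 + η²/3) { [same bracket] + (4/3)[S² τ_s + (1−S²) τ_f] }

with ω the 31P Larmor angular frequency (rad/s), σ the CSA as a
dimensionless fraction (ppm × 10⁻⁶) and η the tensor asymmetry.  Default
constants (`DEFAULT_P31_PARAMS`): ω = 2π × 242 MHz (14.1 T), σ = 160 ppm,
η = 0.57, S = 0.2, values appropriate for heterogeneous synaptic-membrane
phosphates.

**Inversion.** In the regime (ωτ_f)² ≫ 1 (validity window [4, 10],
configurable; results outside it are flagged, never suppressed) and
(ωτ_s)² ≫ (ωτ_f)², the slow spectral-density terms are negligible
(verified ~10⁻¹⁵ vs 10⁻¹⁰ for the defaults) and the system becomes
analytically invertible: τ_f is linear in T1 (ω cancels), and τ_s follows
from R2 − R1/2.  Inverting full-model data with the simplified equations
incurs a deterministic bias of 1/(ωτ_f)² relative in τ_f (13% at
(ωτ_f)² = 7.5, bounded by 35% over the validity window) and < 1% in τ_s;
the test suite pins these bounds.  A negative inverted τ_s (T2
inconsistent with the τ_f floor) is reported as-is with `valid=False`.

**Exponential fits.** T2: I(t) = I0·exp(−t/τ2).  T1 inversion recovery:
I(t) = I0·(1 − β·exp(−t/τ1)) with β free by default — real
inversion-recovery data rarely achieve the ideal β = 2, which remains
available via `fix_beta=2`.  Fits use lmfit with deterministic
initial guesses (log-linear regression for T2, zero-crossing heuristic
for T1); no random restarts, so results are reproducible bit-for-bit.

**Uncertainty propagation.** First-order propagation uses constants
C1–C4:

    στ_f = (C1/ω²)·σ_T1
    στ_s = sqrt[ (C2/T2²)² σ_T2² + (C3/T1² − C4)² σ_T1² ]

Two derivation modes ship because the published C1 = (2/15)ω²σ²(1+η²/3)
omits the (1−S²) factor that the implemented τ_f inversion actually
carries.  `as_printed` (default) matches the published constants
(C1 = 8.746×10⁹ s⁻², C2 = 4.288×10⁻⁹ s² for the defaults) and therefore
overestimates στ_f by 1/(1−S²) ≈ 4%; `self_consistent` multiplies C1 by
(1−S²) so that all four constants are exactly the partial derivatives of
the implemented inversion.  C3 = C2/2 and C4 = (1−S²)²(C1/ω²)/S² are
derived by differentiation in both modes (2.14×10⁻⁹ and 8.72×10⁻⁸ for the
defaults); published values of the same constants differ by 3–10%,
consistent with rounding and the same (1−S²) placement ambiguity, and are
not reproducible exactly from the other published constants under any
consistent convention.  Monte-Carlo resampling agrees with the analytic
propagation to within a few percent at ≤ 5% relative input errors.

**Δτ.** Sample-minus-control differences combine uncertainties in
quadrature; positive Δτ means the peptide restricts the motion.  The
temperature metadata of sample and control must match.

## Dipolar recoupling and distance estimation (`memfibril.dipolar`)

**Couplings.** d = (μ0/4π)·γ_a·γ_b·ħ/(2π r³) in Hz with γ(13C) =
6.7283×10⁷ and γ(31P) = 1.0839×10⁸ rad s⁻¹ T⁻¹ (60.8 Hz for a 5 Å
13C–13C pair).

**PITHIRDs-CT.** The isolated-pair constant-time signal is modeled as the
powder average S(t)/S0 = ⟨cos(κ·π·d·P₂(cosθ)·t)⟩, evaluated by 256-node
Gauss–Legendre quadrature in cosθ (a seeded Monte-Carlo powder average is
retained purely as a test oracle).  The effective recoupling scaling κ
depends on pulse-sequence details outside this model; it is a single
documented constant (κ = 0.25, exposed as a parameter) chosen so the
~4.8 Å parallel-in-register curve decays on the tens-of-milliseconds
scale over the 0–61.4 ms constant-time window.  Distance ordering,
grid matching and recovery are insensitive to κ because observed and
candidate curves share the simulator.  Multi-spin couplings and
relaxation damping are not modeled; an optional exponential damping
factor (`scale_fit=True`) absorbs imperfect constant-time compensation.

**REDOR.** The isolated-pair build-up is universal in λ = N·T_r·d.  The
fast path is the closed Bessel form S/S0 = (√2π/4)·J₁∕₄(√2λ)·J₋₁∕₄(√2λ);
a brute-force powder integration of the accumulated phase
ΔΦ = 4√2·λ·sinβcosβ·sinα is kept as an independent oracle (agreement
< 10⁻³).  ΔS/S0 starts at 0, approaches 1, and oscillates within
[0, 1.1].  (S0, S1) spectral pairs are converted internally via
ΔS/S0 = (S0−S1)/S0.  A low REDOR plateau is reported as a diagnostic of a
large non-contacting population, not converted into a population
fraction: that conversion requires a binding model this package does not
assume.

**Distance estimation.** Noise-weighted RSS against the simulated family
on a 4.0–8.0 Å grid (0.1 Å step); exact ties break toward larger
(conservative) r.  Contact classes: strong ≤ 5.5 Å < medium ≤ 7 Å <
little (configurable).  An overall-increasing PITHIRDs curve is
unphysical and is classified `little` with a warning.  Seeded recovery:
median error ≤ 0.3 Å at per-point noise σ = 0.05 across 4.5–7 Å.

## Isotope-dilution spin diffusion (`memfibril.spindiff`)

**Volumes and noise.** Peak volumes are inclusive rectangular window sums
(default 1.5 × 1.5 ppm around the center); ppm axes are normalized to the
descending NMR convention on input.  Spectral noise is the SD of volumes
of 10 peak-free windows tiled on a coarse grid (disjoint by
construction), drawn without replacement with a recorded seed.

**Reduction statistic.** Reduction = (V1,d/V0,d)/(V1,n/V0,n) × 100% with
the four-term first-order uncertainty (partial derivatives of the double
ratio, diluted-spectrum noise on diluted volumes and non-diluted noise on
the rest).  Classification thresholds — intrastrand ≥ 75%, interstrand
≤ 50%, ambiguous between — sit midway between the theoretical 100%
(intrastrand) and ≤ 50% (any interstrand model) expectations and are
configurable; a point estimate whose ±1σ interval straddles the opposing
threshold is downgraded to ambiguous.

**Dilution expectation and its normalization ambiguity.** Under
independent Bernoulli(p) labeling, an interstrand crosspeak requires both
members of a neighboring-strand pair to be labeled: expected
diluted/non-diluted intensity p² (25% at p = 0.5), verified by seeded
Monte Carlo on a 1-D strand lattice.  Strictly, p² applies to the
absolute crosspeak intensity; if the diagonal reference itself scaled
with the labeled fraction p, the diagonal-normalized ratio would be p
(50%).  The package implements the stated p² expectation and keeps both
conventions explicit rather than silently correcting either: the
spectrum generator's `diagonal_scaling` parameter defaults to
`"reference"` (diagonals unscaled, measured reduction = p²) with
`"labeled_fraction"` (diagonals × p, measured reduction = p) available.

**Secondary shifts.** Deviation = (δCβ_obs − δCβ_rc) − (δCα_obs −
δCα_rc) against a bundled random-coil 13C reference table
(Wishart-style DSS-referenced values, `data/random_coil_c13.csv`).
Positive deviations call β-strand; a ±0.5 ppm band around zero is
undetermined, as are residues lacking either shift (glycine Cβ) or absent
from the table.

## TEM mass-per-length (`memfibril.mpl`)

**MPL.** Dark-field scattering intensity is proportional to mass, so
MPL = (net fibril intensity)/(net TMV intensity) × 131 kDa/nm with
tobacco mosaic virus as internal standard.  The source equation as
typeset has the reciprocal ratio, which inverts the physics; the package
defaults to the physically consistent `physical` convention and preserves
the typeset form behind `convention="as_printed"`.  The identity case
(equal net intensities → 131 kDa/nm) is convention-independent.  Region
selection from images is out of scope: the module consumes integrated
intensity tables.

**Mixture fit.** Fibrils bundle, so the MPL histogram is fit by a
Gaussian mixture with means constrained to integer multiples k·u of a
single-filament unit, shared width, and optionally fitted u.  The EM
implementation is deterministic (uniform initial weights, MAD-based
initial width) and asserts a non-decreasing log-likelihood at every
iteration; non-convergence raises with the last state.  Components with
weight > 0.15 are reported dominant.  Unit recovery is within 5% at
n = 500 and width/u ≈ 0.16.

**Symmetry.** fold = round(u·rise/monomer_mw) with defaults 4.33 kDa
(Aβ(1-40)) and 0.47 nm cross-β rise.  A unit of 18.8 kDa/nm gives
fold = 2 with ~2% residual mismatch; the mismatch is always reported (and
flagged above 25%) rather than asserting exactness, since isotope
labeling and rise variations shift the ideal value by a few percent.

## Plate-reader assays (`memfibril.assays`)

**ThT kinetics.** F(t) = F0 + A/(1+exp(−k(t−t_half))), least squares with
deterministic initialization.  The lag period uses the tangent-intercept
convention lag = t_half − 2/k (standard for ThT kinetics; the
10%-amplitude alternative t_half − ln9/k is available).  lag_se combines
the t_half and k errors including their covariance by the delta method.
Traces without net growth raise a flagged failure; traces that have not
reached 90% of the fitted plateau mark the lag as a lower bound.  Fit
standard errors and replicate SDs answer different questions; where
replicates exist both should be reported.

**Binding.** free% = 100·(C_sup,sample − C_sup,control)/C_initial; the
default output is the membrane-bound complement 100 − free% because the
typeset equation labels the free fraction "Membrane-bound%"
(`convention="as_printed"` preserves the typeset form; the two always sum
to 100).  Negative corrected concentrations clip to zero with a warning.
A BSA standard-curve helper (ordinary least squares; a 4-parameter
logistic is deliberately not used for this linear-range assay) converts
absorbances to concentrations.

**Viability.** (A_sample − A_background)/(A_control − A_background) ×
100%, invariant under common rescaling; values above 100% are reported
as-is.

**Stability.** Two-state sigmoid f(c) = b + a/(1+exp((c−C½)/w)) over the
2.27–5.46 M GdnHCl range; C½ with standard error; recovery within 0.2 M
at 3% noise.  Lower C½ ranks a fibril less stable.  Fractions that rise
with denaturant are fitted but flagged.

**Significance.** Two-sided two-sample t test, Welch by default.  Star
convention (configurable): *** p < 0.001, ** p < 0.01, * p < 0.1.  Two
zero-variance groups with equal means return p = 1.

## Synthetic data (`memfibril.synthetic`)

Generators are pure functions of their arguments (same seed ⇒ identical
output).  Default noise is Gaussian with SD 2% of the maximum signal,
mimicking the scatter typical of the underlying measurements; TEM
intensities use Poisson counting noise.  Ground-truth defaults encode the
study conditions: τ_f ≈ 1.5–1.8 ns and τ_s ≈ 4–4.5 µs with a programmed
+0.3 ns headgroup restriction, distances on the 4–8 Å grid, 1:1 dilution,
MPL unit 18.8 kDa/nm with bundles of 2–3 filaments, and ThT lag presets
(aqueous 28.5 h; rSPM 3/12/18-month 39.4/37.2/40.5 h) carried as data for
demonstrations, not assertions.

Relaxation sets are computed from the **full** rate model so the
simplified inversion is tested with its approximation error included.
What the generators do *not* emulate — and hence what passing tests do
not demonstrate about real data: multi-spin dipolar networks and
relaxation damping in dephasing curves; overlapping resonances, baseline
roll and t1-noise ridges in 2D spectra; lipid-species heterogeneity and
temperature drifts in relaxation series; secondary nucleation or
non-logistic growth in ThT traces; stain/defocus gradients in TEM
intensities.

## Problem sizes

The seeded studies in the test-suite use 20–100 replicates per condition,
10⁵–10⁶ Monte-Carlo draws for propagation/dilution checks, 0.1 Å distance
grids, and 600×600–800×800-point synthetic spectra — sizes at which every
recovery check is resolved well inside its tolerance while the whole
suite runs in a few minutes on one CPU.

## Known limitations

- The dephasing model is strictly isolated-pair; crowded labeling
  schemes need multi-spin simulation outside this package's scope.
- The PITHIRDs κ constant is a calibration placeholder: absolute
  distances from real spectrometer data require matching κ to the pulse
  sequence actually used.
- The simplified relaxation inversion inherits its documented bias near
  the edges of the (ωτ_f)² window; for (ωτ_f)² < 4 a numerical inversion
  of the full model would be required.
- Random-coil shift references vary by a few tenths of a ppm between
  published tables; the ±0.5 ppm undetermined band absorbs this, but
  borderline β-strand calls should not be over-interpreted.
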