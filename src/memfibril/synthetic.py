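"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package consumes delimited-text-style inputs
(decay series, dephasing curves, 2D spectra, intensity tables, kinetics
traces).  The generators here emulate each of them from explicit
ground-truth parameters so the whole pipeline is testable end to end:

- relaxation sets are computed from the FULL two-timescale rate model, so
  the simplified inversion is genuinely exercised (approximation error
  included);
- dephasing curves come from the same powder-averaged simulators used in
  fitting, plus i.i.d. Gaussian noise;
- 2D spectra are sums of Gaussian peaks on a ppm grid; the diluted
  counterpart scales interstrand crosspeaks by p^2, diagonals by p and
  intrastrand crosspeaks by 1, per the independent-labeling model;
- MPL samples are drawn from a Gaussian mixture at integer multiples of a
  unit MPL;
- ThT traces are logistic curves parameterized directly by the lag period
  (t_half = lag + 2/k).

All generators are pure functions of their arguments: the same seed gives
identical output.  Default noise is Gaussian with SD 2% of the maximum
signal, mimicking the scatter of the underlying measurements; TEM
intensities may instead use Poisson counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .assays import ThTTrace
from .dipolar import (
    DephasingCurve,
    dipolar_coupling,
    redor_universal,
    simulate_pithirds_decay,
)
from .relaxation import (
    DEFAULT_P31_PARAMS,
    RelaxationSeries,
    SpinSystemParams,
    full_rate_model,
)
from .spindiff import Spectrum2D

#: ThT lag-period ground truths (hours) for the experimental conditions:
#: fibrillation of 10 uM Abeta(1-40) in aqueous buffer and in the presence
#: of rat synaptic plasma membranes (rSPMs) of three tissue ages.
#: Presets are data for demos, not assertions.
THT_LAG_PRESETS = {
    "aqueous": 28.5,
    "rSPM-3mo": 39.4,
    "rSPM-12mo": 37.2,
    "rSPM-18mo": 40.5,
}

DEFAULT_NOISE_FRACTION = 0.02  # Gaussian noise SD as a fraction of max signal


@dataclass(frozen=True)
class GeneratorSpec:
    """Record of the ground truth behind one generated dataset."""

    seed: int
    noise_model: Literal["gaussian", "poisson"]
    parameters: dict
    n: int


@dataclass(frozen=True)
class Peak2D:
    """A Gaussian peak for 2D spectrum synthesis.

    ``kind`` controls the dilution scaling: 'diagonal' scales by p,
    'interstrand' crosspeaks by p^2, 'intrastrand' crosspeaks by 1.
    """

    center: tuple[float, float]  # ppm
    volume: float  # integrated (grid-sum) volume
    widths: tuple[float, float] = (0.3, 0.3)  # Gaussian SD, ppm
    kind: Literal["diagonal", "intrastrand", "interstrand"] = "intrastrand"


def gen_relaxation_set(
    tau_f: float,
    tau_s: float,
    control_tau_f: float,
    control_tau_s: float,
    params: SpinSystemParams = DEFAULT_P31_PARAMS,
    delays_t1: np.ndarray | None = None,
    delays_t2: np.ndarray | None = None,
    noise_sd: float = DEFAULT_NOISE_FRACTION,
    seed: int = 0,
    temperature: float = 298.0,
    i0: float = 100.0,
) -> dict[str, RelaxationSeries]:
    """Paired sample/control T1 and T2 decay series from the full rate model.

    tau_f in the 0.5-5 ns and tau_s in the 0.5-20 us physical ranges.
    T1 = 1/R1 and T2 = 1/R2 are computed from the full quadratic
    expressions; the T2 decay is sampled as I0 exp(-t/T2) and the T1
    inversion recovery as I0 (1 - 2 exp(-t/T1)), with Gaussian noise of SD
    ``noise_sd * i0``.  Delay grids default to 8 log-ish spaced points
    spanning ~3 time constants.
    """
    for name, val, lo, hi in (
        ("tau_f", tau_f, 0.5e-9, 5e-9),
        ("tau_s", tau_s, 0.5e-6, 20e-6),
        ("control_tau_f", control_tau_f, 0.5e-9, 5e-9),
        ("control_tau_s", control_tau_s, 0.5e-6, 20e-6),
    ):
        if not lo <= val <= hi:
            raise ValueError(f"{name}={val} outside physical range [{lo}, {hi}] s")
    rng = np.random.default_rng(seed)
    out: dict[str, RelaxationSeries] = {}
    for role, tf, ts in (
        ("sample", tau_f, tau_s),
        ("control", control_tau_f, control_tau_s),
    ):
        r1, r2 = full_rate_model(tf, ts, params)
        t1, t2 = 1.0 / r1, 1.0 / r2
        d1 = delays_t1 if delays_t1 is not None else np.linspace(0.02, 3.0, 8) * t1
        d2 = delays_t2 if delays_t2 is not None else np.linspace(0.02, 3.0, 8) * t2
        y1 = i0 * (1.0 - 2.0 * np.exp(-d1 / t1)) + rng.normal(0, noise_sd * i0, d1.size)
        y2 = i0 * np.exp(-d2 / t2) + rng.normal(0, noise_sd * i0, d2.size)
        out[f"{role}_T1"] = RelaxationSeries(
            "T1", d1, y1, temperature=temperature, label=f"{role} T1"
        )
        out[f"{role}_T2"] = RelaxationSeries(
            "T2", d2, y2, temperature=temperature, label=f"{role} T2"
        )
    return out


def gen_dephasing(
    r: float,
    experiment: Literal["PITHIRDS_CT", "REDOR"] = "PITHIRDS_CT",
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rotor_period: float = 1.0 / 8000.0,
) -> DephasingCurve:
    """A simulated dephasing curve at distance r (A) with Gaussian noise.

    Default PITHIRDs time grid: 17 points over 0-61.4 ms (constant-time
    window); default REDOR grid: every 16 rotor periods at 8 kHz MAS up to
    24 ms dephasing.
    """
    rng = np.random.default_rng(seed)
    if experiment == "PITHIRDS_CT":
        if times is None:
            times = np.linspace(0.0, 61.44e-3, 17)
        curve = simulate_pithirds_decay(r, times)
    else:
        if times is None:
            times = np.arange(0, 193, 16) * rotor_period
        d = dipolar_coupling(r, "CP")
        curve = DephasingCurve(
            experiment="REDOR",
            times=np.asarray(times, dtype=float),
            signal=redor_universal(np.asarray(times, dtype=float) * d),
        )
    noisy = curve.signal + rng.normal(0.0, noise_sd, curve.signal.size)
    sigma = np.full(curve.signal.size, noise_sd) if noise_sd > 0 else None
    return DephasingCurve(
        experiment=curve.experiment,
        times=curve.times,
        signal=noisy,
        sigma=sigma,
        label=f"synthetic r={r:.2f} A",
    )


def gen_spectrum2d(
    peaks: Sequence[Peak2D],
    dilution_p: float = 0.5,
    axis_f1: np.ndarray | None = None,
    axis_f2: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    diagonal_scaling: Literal["reference", "labeled_fraction"] = "reference",
) -> tuple[Spectrum2D, Spectrum2D]:
    """A (non-diluted, diluted) pair of synthetic 2D spectra.

    Peak amplitudes are scaled so that the plain grid sum of a fully
    enclosed peak equals its nominal volume.  In the diluted spectrum,
    interstrand crosspeaks scale by p^2 and intrastrand crosspeaks by 1.

    ``diagonal_scaling`` selects the normalization convention for diagonal
    peaks (the spin-resource references of the Reduction statistic), a
    genuinely ambiguous choice: with ``reference`` (default) diagonals are
    left unscaled, so the measured diagonal-normalized reduction of an
    interstrand crosspeak equals the stated pair-product expectation p^2
    (25% at 1:1 dilution); with ``labeled_fraction`` diagonals scale by p
    (diagonal intensity proportional to the labeled population), in which
    case the same measured reduction is p, not p^2.  Neither convention is
    "corrected" to the other — see the methods note.

    Peaks sharing a center are merged by volume addition.  Independent
    Gaussian noise of SD ``noise_sd`` is added to each spectrum.
    """
    if not 0.0 < dilution_p <= 1.0:
        raise ValueError("dilution_p must lie in (0, 1]")
    f1 = axis_f1 if axis_f1 is not None else np.arange(80.0, 0.0, -0.1)
    f2 = axis_f2 if axis_f2 is not None else np.arange(80.0, 0.0, -0.1)
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    df1 = abs(float(np.median(np.diff(f1))))
    df2 = abs(float(np.median(np.diff(f2))))

    merged: dict[tuple[float, float], Peak2D] = {}
    for pk in peaks:
        if not (
            f1.min() <= pk.center[0] <= f1.max()
            and f2.min() <= pk.center[1] <= f2.max()
        ):
            raise ValueError(f"peak center {pk.center} outside the ppm grid")
        if pk.center in merged:
            old = merged[pk.center]
            merged[pk.center] = Peak2D(
                pk.center, old.volume + pk.volume, old.widths, old.kind
            )
        else:
            merged[pk.center] = pk

    rng = np.random.default_rng(seed)
    diag_scale = 1.0 if diagonal_scaling == "reference" else dilution_p
    if diagonal_scaling not in ("reference", "labeled_fraction"):
        raise ValueError(f"unknown diagonal_scaling {diagonal_scaling!r}")
    scale = {
        "diagonal": diag_scale,
        "intrastrand": 1.0,
        "interstrand": dilution_p**2,
    }
    spectra = []
    for diluted in (False, True):
        grid = np.zeros((f1.size, f2.size))
        for pk in merged.values():
            w1, w2 = pk.widths
            amp = pk.volume * df1 * df2 / (2.0 * math.pi * w1 * w2)
            if diluted:
                amp *= scale[pk.kind]
            g1 = np.exp(-0.5 * ((f1 - pk.center[0]) / w1) ** 2)
            g2 = np.exp(-0.5 * ((f2 - pk.center[1]) / w2) ** 2)
            grid += amp * np.outer(g1, g2)
        grid += rng.normal(0.0, noise_sd, grid.shape) if noise_sd > 0 else 0.0
        spectra.append(
            Spectrum2D(f1, f2, grid, label="diluted" if diluted else "non-diluted")
        )
    return spectra[0], spectra[1]


def gen_mpl_sample(
    u: float = 18.8,
    weights_over_k: Sequence[float] = (0.0, 0.5, 0.5),
    width: float = 3.0,
    n: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """MPL values (kDa/nm) from a mixture at integer multiples of u.

    ``weights_over_k[i]`` is the weight of component k = i + 1.  Width 0
    puts every value exactly at k * u.
    """
    weights = np.asarray(weights_over_k, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    k = rng.choice(np.arange(1, weights.size + 1), size=n, p=weights)
    return k * u + rng.normal(0.0, width, n)


def gen_mpl_intensities(
    true_mpl: float,
    n: int = 500,
    tmv_counts: float = 10_000.0,
    background_counts: float = 2_000.0,
    seed: int = 0,
) -> list:
    """Poisson-noise dark-field intensity quartets with a known true MPL.

    Fibril and TMV region counts are Poisson-distributed around means
    proportional to mass (TMV at 131 kDa/nm), on top of a common
    background level; returns a list of :class:`~memfibril.mpl.MPLMeasurement`.
    """
    from .mpl import TMV_MPL, MPLMeasurement

    rng = np.random.default_rng(seed)
    fibril_mean = tmv_counts * true_mpl / TMV_MPL
    out = []
    for _ in range(n):
        out.append(
            MPLMeasurement(
                i_fibril=float(rng.poisson(fibril_mean + background_counts)),
                i_bg_fibril=float(rng.poisson(background_counts)),
                i_tmv=float(rng.poisson(tmv_counts + background_counts)),
                i_bg_tmv=float(rng.poisson(background_counts)),
            )
        )
    return out


def gen_tht_trace(
    lag: float,
    k: float = 0.5,
    F0: float = 100.0,
    A: float = 1000.0,
    noise_sd: float = 0.0,
    n_points: int = 60,
    t_max: float | None = None,
    seed: int = 0,
    replicate_id: str = "",
) -> ThTTrace:
    """A logistic ThT trace with tangent-intercept lag ground truth.

    t_half = lag + 2/k; the default time window extends far enough past
    t_half for the plateau to be visible.
    """
    if k <= 0:
        raise ValueError("growth rate must be positive")
    t_half = lag + 2.0 / k
    if t_max is None:
        t_max = t_half + 8.0 / k
    times = np.linspace(0.0, t_max, n_points)
    rng = np.random.default_rng(seed)
    signal = F0 + A / (1.0 + np.exp(-k * (times - t_half)))
    signal = signal + rng.normal(0.0, noise_sd, n_points)
    return ThTTrace(times=times, fluorescence=signal, replicate_id=replicate_id)


def gen_stability_data(
    c_half: float,
    width: float = 0.3,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state denaturation data over the 2.27-5.46 M GdnHCl range."""
    c = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else np.linspace(2.27, 5.46, 8)
    )
    rng = np.random.default_rng(seed)
    f = 1.0 / (1.0 + np.exp((c - c_half) / width))
    f = np.clip(f + rng.normal(0.0, noise_sd, c.size), 0.0, 1.1)
    return c, f
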