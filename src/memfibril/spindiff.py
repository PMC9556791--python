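"""2D spin-diffusion crosspeak quantification and isotope-dilution statistics.

Long-mixing 2D 13C-13C spin diffusion produces crosspeaks between carbons
within ~6 A, whether the contact is within one peptide strand or between
neighboring strands of a fibril.  Diluting labeled with unlabeled peptide
1:1 distinguishes the two: an intramolecular (intrastrand) crosspeak needs
only one labeled molecule and survives dilution, while an intermolecular
(interstrand) crosspeak requires two adjacent labeled molecules and is
strongly attenuated.  Under independent Bernoulli(p) labeling of strands,
the expected diluted/non-diluted intensity of an interstrand crosspeak is
p^2 (25% at p = 1/2).  Note the normalization ambiguity: the
p^2 figure refers to absolute crosspeak intensity; after division by the
diagonal (which itself scales by p) the ratio would be p.  This module
implements the pair-product p^2 expectation as stated.

The per-contact observable is the Reduction statistic

    Reduction = (V1,d / V0,d) / (V1,n / V0,n) x 100%

(crosspeak over diagonal, diluted over non-diluted) with a first-order
four-term propagated uncertainty from the spectral noise of each spectrum.
Crosspeaks retaining ~100% are intrastrand; strongly reduced ones are
interstrand.

Also included: residue-wise secondary chemical-shift deviations
(dCb - dCb_rc) - (dCa - dCa_rc); positive values indicate beta-strand
conformation.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class Spectrum2D:
    """A 2D spectrum on rectangular ppm grids.

    Axes are stored in descending ppm order (NMR convention); ascending
    input axes are flipped on construction, together with the intensity
    matrix (rows = f1, columns = f2).
    """

    axis_f1: np.ndarray
    axis_f2: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.axis_f1 = np.asarray(self.axis_f1, dtype=float)
        self.axis_f2 = np.asarray(self.axis_f2, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis_f1.size, self.axis_f2.size):
            raise ValueError("intensity shape must match (len(f1), len(f2))")
        for name in ("axis_f1", "axis_f2"):
            ax = getattr(self, name)
            d = np.diff(ax)
            if np.all(d > 0):  # ascending: normalize to descending
                setattr(self, name, ax[::-1].copy())
                if name == "axis_f1":
                    self.intensity = self.intensity[::-1, :].copy()
                else:
                    self.intensity = self.intensity[:, ::-1].copy()
            elif not np.all(d < 0):
                raise ValueError(f"{name} must be strictly monotone")


@dataclass
class VolumeResult:
    """Integrated intensity in a rectangular ppm window around a peak."""

    center: tuple[float, float]
    window: tuple[float, float]  # half-widths per axis (default 0.75 -> 1.5 total)
    volume: float
    noise_sd: float = 0.0


@dataclass
class NoiseEstimate:
    """SD of volumes of randomly placed peak-free windows (seeded)."""

    noise_sd: float
    regions: list[tuple[float, float]]
    seed: int

    def __float__(self) -> float:
        return self.noise_sd


@dataclass
class DilutionQuartet:
    """Crosspeak/diagonal volumes from non-diluted and diluted spectra."""

    v1_n: float  # crosspeak, non-diluted
    v0_n: float  # diagonal, non-diluted
    v1_d: float  # crosspeak, diluted
    v0_d: float  # diagonal, diluted
    delta_n: float = 0.0  # noise SD, non-diluted spectrum
    delta_d: float = 0.0  # noise SD, diluted spectrum

    def __post_init__(self) -> None:
        if self.v0_n <= 0 or self.v0_d <= 0:
            raise ValueError("diagonal volumes must be positive")


@dataclass
class ReductionResult:
    reduction: float  # percent
    uncertainty: float  # percent
    contact_class: Literal["intrastrand", "interstrand", "ambiguous"]


@dataclass
class ShiftRecord:
    """Residue-specific 13C chemical shifts and the derived beta call."""

    residue: str  # e.g. "F19": one-letter code + sequence index
    delta_ca: float | None = None
    delta_cb: float | None = None
    delta_co: float | None = None
    deviation: float | None = None
    call: Literal["beta", "non_beta", "undetermined"] = "undetermined"

    @property
    def aa(self) -> str:
        return self.residue[0].upper()


def integrate_peak_volume(
    spec: Spectrum2D,
    center: tuple[float, float],
    window: tuple[float, float] = (0.75, 0.75),
) -> VolumeResult:
    """Sum intensities over an inclusive rectangular ppm window.

    ``window`` holds half-widths, so the default covers 1.5 x 1.5 ppm.
    """
    masks = []
    for ax_name, ax, c, hw in (
        ("f1", spec.axis_f1, center[0], window[0]),
        ("f2", spec.axis_f2, center[1], window[1]),
    ):
        lo, hi = c - hw, c + hw
        if lo < ax.min() or hi > ax.max():
            raise ValueError(
                f"integration window [{lo}, {hi}] ppm exceeds the {ax_name} "
                f"axis range [{ax.min()}, {ax.max()}] ppm"
            )
        masks.append((ax >= lo) & (ax <= hi))
    volume = float(spec.intensity[np.ix_(masks[0], masks[1])].sum())
    return VolumeResult(center=tuple(center), window=tuple(window), volume=volume)


def estimate_spectral_noise(
    spec: Spectrum2D,
    peak_centers: Sequence[tuple[float, float]],
    n_regions: int = 10,
    window: tuple[float, float] = (0.75, 0.75),
    exclusion: float = 1.5,
    seed: int = 0,
) -> NoiseEstimate:
    """SD of integrated volumes of n_regions disjoint peak-free windows.

    Candidate windows tile the spectrum on a coarse grid (one window
    width apart, guaranteeing disjointness); candidates whose center lies
    within ``exclusion`` ppm (per axis) of any peak center are removed and
    ``n_regions`` survivors are drawn without replacement with the given
    seed.  Same seed and spectrum give identical regions.
    """
    hw1, hw2 = window
    c1 = np.arange(spec.axis_f1.max() - hw1, spec.axis_f1.min() + hw1, -2 * hw1)
    c2 = np.arange(spec.axis_f2.max() - hw2, spec.axis_f2.min() + hw2, -2 * hw2)
    candidates = [
        (a, b)
        for a in c1
        for b in c2
        if all(
            abs(a - p1) > exclusion or abs(b - p2) > exclusion
            for p1, p2 in peak_centers
        )
    ]
    if len(candidates) < n_regions:
        raise ValueError(
            f"only {len(candidates)} disjoint peak-free windows available, "
            f"need {n_regions}; try a smaller window"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_regions, replace=False)
    regions = [candidates[i] for i in idx]
    volumes = [integrate_peak_volume(spec, c, window).volume for c in regions]
    return NoiseEstimate(
        noise_sd=float(np.std(volumes, ddof=1)), regions=regions, seed=seed
    )


def reduction_statistic(
    q: DilutionQuartet,
    thresholds: tuple[float, float] = (75.0, 50.0),
) -> ReductionResult:
    """Isotope-dilution Reduction statistic with propagated uncertainty.

    Reduction = (v1_d / v0_d) / (v1_n / v0_n) x 100%.  The uncertainty is
    the first-order quadrature over the four volumes with the spectral
    noise of the spectrum each was measured in.  Classification: reduction
    >= 75% -> intrastrand, <= 50% -> interstrand, otherwise ambiguous; a
    point estimate whose +/- 1 sigma interval straddles the opposing
    threshold is downgraded to ambiguous.
    """
    if q.v1_n == 0:
        raise ValueError("non-diluted crosspeak volume must be nonzero")
    red = (q.v1_d / q.v0_d) / (q.v1_n / q.v0_n) * 100.0
    unc = (
        math.sqrt(
            (q.v1_d / (q.v0_d * q.v1_n)) ** 2 * q.delta_n**2
            + (q.v0_n / (q.v0_d * q.v1_n)) ** 2 * q.delta_d**2
            + (q.v1_d * q.v0_n / (q.v0_d * q.v1_n**2)) ** 2 * q.delta_n**2
            + (q.v1_d * q.v0_n / (q.v1_n * q.v0_d**2)) ** 2 * q.delta_d**2
        )
        * 100.0
    )
    intra_min, inter_max = thresholds
    if red >= intra_min:
        cls = "ambiguous" if red - unc < inter_max else "intrastrand"
    elif red <= inter_max:
        cls = "ambiguous" if red + unc > intra_min else "interstrand"
    else:
        cls = "ambiguous"
    return ReductionResult(reduction=red, uncertainty=unc, contact_class=cls)


def dilution_expectation(
    p: float, model: Literal["pair_product"] = "pair_product"
) -> float:
    """Expected diluted/non-diluted interstrand crosspeak intensity (%).

    Under independent Bernoulli(p) labeling of strands, an interstrand
    crosspeak requires both members of a neighboring-strand pair to be
    labeled: expectation = p^2 x 100% (25% at 1:1 dilution).
    """
    if model != "pair_product":
        raise ValueError(f"unknown model {model!r}")
    if not 0.0 < p <= 1.0:
        raise ValueError("label fraction must lie in (0, 1]")
    return p**2 * 100.0


def dilution_expectation_mc(
    p: float, n_pairs: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo check of the pair-product expectation on a 1-D lattice.

    Strands on a linear fibril lattice are labeled i.i.d. Bernoulli(p);
    returns the percentage of nearest-neighbor pairs with both members
    labeled (relative to the all-labeled case, which has all pairs active).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("label fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_pairs + 1) < p
    both = labels[:-1] & labels[1:]
    return float(both.mean() * 100.0)


def load_random_coil_table() -> pd.DataFrame:
    """Bundled random-coil 13C chemical shifts (ppm), indexed by one-letter code."""
    with importlib.resources.files("memfibril.data").joinpath(
        "random_coil_c13.csv"
    ).open() as fh:
        table = pd.read_csv(fh)
    return table.set_index("aa")


def secondary_shift_deviation(
    records: Sequence[ShiftRecord],
    random_coil_table: pd.DataFrame | None = None,
    band: float = 0.5,
) -> list[ShiftRecord]:
    """Annotate records with (dCb - dCb_rc) - (dCa - dCa_rc) and a beta call.

    Positive deviations indicate beta-strand conformation; calls within
    +/- ``band`` ppm of zero are 'undetermined'.  Records lacking either
    shift (e.g. glycine Cb) or absent from the reference table stay
    'undetermined' with a warning.
    """
    table = load_random_coil_table() if random_coil_table is None else random_coil_table
    out = []
    for rec in records:
        if rec.aa not in table.index:
            warnings.warn(
                f"residue type {rec.aa!r} not in the random-coil table; "
                f"{rec.residue} left undetermined",
                stacklevel=2,
            )
            rec.deviation, rec.call = None, "undetermined"
            out.append(rec)
            continue
        row = table.loc[rec.aa]
        if rec.delta_ca is None or rec.delta_cb is None or pd.isna(row["cb"]):
            rec.deviation, rec.call = None, "undetermined"
            out.append(rec)
            continue
        dev = (rec.delta_cb - float(row["cb"])) - (rec.delta_ca - float(row["ca"]))
        rec.deviation = dev
        if dev > band:
            rec.call = "beta"
        elif dev < -band:
            rec.call = "non_beta"
        else:
            rec.call = "undetermined"
        out.append(rec)
    return out
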