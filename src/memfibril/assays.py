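"""Plate-reader assay quantification for amyloid fibrillation studies.

- ThT fluorescence kinetics: a logistic fit F(t) = F0 + A / (1 + exp(-k (t
  - t_half))) whose lag period uses the tangent-intercept convention
  lag = t_half - 2/k (the intercept of the maximal-slope tangent with the
  baseline).  An alternative 10%-of-amplitude convention is available.
- BCA membrane binding: the background-corrected supernatant (free)
  fraction of peptide relative to the initial concentration; the default
  output is the membrane-bound complement.
- MTT cell viability: (A_sample - A_background) / (A_control -
  A_background) x 100%.
- GdnHCl fibril stability: two-state sigmoid fit of remaining fibril
  fraction vs denaturant concentration; the midpoint C1/2 orders fibril
  types by stability (lower C1/2 = less stable).
- Group significance: two-sample t test (Welch by default) with the star
  annotation convention * p < 0.1, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from lmfit import Model
from scipy import stats

from .relaxation import FitError


@dataclass
class ThTTrace:
    """A thioflavin-T fluorescence time course (times in hours)."""

    times: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 10:
            raise ValueError("need at least 10 points spanning lag and growth")
        if self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class KineticsFit:
    """Logistic ThT fit; lag = t_half - 2/k (tangent-intercept)."""

    F0: float
    A: float
    k: float  # 1/h
    t_half: float  # h
    lag: float  # h
    lag_se: float  # h
    lag_is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("growth rate k must be positive")


@dataclass
class AssayResult:
    kind: Literal["binding", "viability", "stability"]
    value: float  # percent
    uncertainty: float = 0.0
    group_label: str = ""
    convention: str = ""


@dataclass
class StabilityFit:
    """Two-state GdnHCl denaturation fit."""

    c_half: float  # M
    c_half_se: float  # M
    width: float  # M
    baseline: float
    amplitude: float
    flagged: bool  # non-monotone data beyond noise


@dataclass
class SignificanceResult:
    t: float
    p: float
    stars: str


def _logistic(t, F0, A, k, t_half):
    return F0 + A / (1.0 + np.exp(-k * (t - t_half)))


def fit_tht_kinetics(
    trace: ThTTrace,
    lag_convention: Literal["tangent", "ten_percent"] = "tangent",
) -> KineticsFit:
    """Fit a logistic to a ThT trace and extract the fibrillation lag period.

    The tangent-intercept lag is t_half - 2/k; the alternative
    ``ten_percent`` convention reports the time at which 10% of the
    amplitude is reached, t_half - ln(9)/k.  The lag standard error comes
    from the fit covariance by the delta method.  If the trace has not
    plateaued (final point below 90% of the fitted amplitude) the lag is
    flagged as a lower bound only.  A trace with no net growth is a
    flagged failure: no silent lag is returned.
    """
    t, y = trace.times, trace.fluorescence
    slope = np.polyfit(t, y, 1)[0]
    if slope <= 0:
        raise FitError(
            "ThT trace shows no fluorescence growth; cannot define a lag period"
        )
    f0_init = float(np.min(y))
    a_init = float(np.max(y) - np.min(y))
    if a_init <= 0:
        raise FitError("flat ThT trace; cannot define a lag period")
    half_level = f0_init + a_init / 2.0
    t_half_init = float(t[np.argmin(np.abs(y - half_level))])
    k_init = 4.0 / max(t[-1] - t[0], 1e-9) * 4.0  # heuristic, refined by fit

    model = Model(_logistic)
    params = model.make_params(F0=f0_init, A=a_init, k=k_init, t_half=t_half_init)
    params["A"].set(min=0.0)
    params["k"].set(min=1e-6)
    result = model.fit(y, params, t=t)
    if not result.success:
        raise FitError(f"ThT logistic fit did not converge: {result.message}")
    k = float(result.params["k"].value)
    t_half = float(result.params["t_half"].value)

    if lag_convention == "tangent":
        lag = t_half - 2.0 / k
        dk = 2.0 / k**2
    elif lag_convention == "ten_percent":
        lag = t_half - math.log(9.0) / k
        dk = math.log(9.0) / k**2
    else:
        raise ValueError(f"unknown lag convention {lag_convention!r}")

    # delta method on lag(t_half, k)
    se_th = result.params["t_half"].stderr or 0.0
    se_k = result.params["k"].stderr or 0.0
    cov = 0.0
    if result.covar is not None:
        names = list(result.var_names)
        if "t_half" in names and "k" in names:
            cov = float(result.covar[names.index("t_half"), names.index("k")])
    var = se_th**2 + dk**2 * se_k**2 + 2.0 * dk * cov
    lag_se = math.sqrt(max(var, 0.0))

    f_final = _logistic(t[-1], *(result.params[p].value for p in ("F0", "A", "k", "t_half")))
    plateau = (f_final - result.params["F0"].value) >= 0.9 * result.params["A"].value
    return KineticsFit(
        F0=float(result.params["F0"].value),
        A=float(result.params["A"].value),
        k=k,
        t_half=t_half,
        lag=lag,
        lag_se=lag_se,
        lag_is_lower_bound=not plateau,
    )


def bca_standard_curve(
    absorbances: Sequence[float], concentrations: Sequence[float]
):
    """Ordinary-least-squares BCA standard curve; returns conc(absorbance).

    Fit of concentration vs absorbance on BSA standards; the returned
    callable converts sample absorbances to peptide concentrations.
    """
    res = stats.linregress(np.asarray(absorbances, float), np.asarray(concentrations, float))

    def predict(a):
        return res.slope * np.asarray(a, dtype=float) + res.intercept

    predict.slope, predict.intercept, predict.rvalue = res.slope, res.intercept, res.rvalue
    return predict


def binding_percentage(
    c_sup_sample: float,
    c_sup_control: float,
    c_initial: float,
    convention: Literal["bound", "as_printed"] = "bound",
    group_label: str = "",
) -> AssayResult:
    """Membrane-binding percentage from BCA supernatant concentrations.

    The background-corrected supernatant concentration (sample minus
    membrane-only control) over the initial peptide concentration is the
    free fraction; ``as_printed`` returns it directly (the form typeset as
    "Membrane-bound%" in the source), while the default ``bound`` returns
    its complement, 100 - free%.  Negative corrected concentrations are
    clipped to zero with a warning.
    """
    if c_initial <= 0:
        raise ValueError("initial concentration must be positive")
    corrected = c_sup_sample - c_sup_control
    if corrected < 0:
        warnings.warn(
            "corrected supernatant concentration is negative; clipping to 0",
            stacklevel=2,
        )
        corrected = 0.0
    free_pct = corrected / c_initial * 100.0
    value = free_pct if convention == "as_printed" else 100.0 - free_pct
    if convention not in ("bound", "as_printed"):
        raise ValueError(f"unknown convention {convention!r}")
    return AssayResult(
        kind="binding", value=value, group_label=group_label, convention=convention
    )


def viability_percentage(
    a_sample: float, a_background: float, a_control: float, group_label: str = ""
) -> AssayResult:
    """MTT cell viability: (A_s - A_bg) / (A_ctrl - A_bg) x 100%.

    Values above 100% are reported as-is.
    """
    if a_control <= a_background:
        raise ValueError("control absorbance must exceed background")
    value = (a_sample - a_background) / (a_control - a_background) * 100.0
    return AssayResult(kind="viability", value=value, group_label=group_label)


def _two_state(c, baseline, amplitude, c_half, width):
    return baseline + amplitude / (1.0 + np.exp((c - c_half) / width))


def stability_curve(
    concentrations: Sequence[float] | np.ndarray,
    remaining_fractions: Sequence[float] | np.ndarray,
) -> StabilityFit:
    """Two-state denaturation fit of remaining fibril fraction vs [GdnHCl].

    Returns the denaturation midpoint C1/2 with its standard error; a
    lower C1/2 means a less stable fibril.  Data that increase with
    denaturant beyond noise are fitted anyway but flagged.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(remaining_fractions, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 denaturant concentrations")
    if np.any((f < 0) | (f > 1.1)):
        raise ValueError("remaining fractions must lie in [0, 1.1]")

    order = np.argsort(c)
    c, f = c[order], f[order]
    flagged = bool(np.polyfit(c, f, 1)[0] > 0)

    half_level = (f.max() + f.min()) / 2.0
    c_half_init = float(c[np.argmin(np.abs(f - half_level))])
    model = Model(_two_state)
    params = model.make_params(
        baseline=float(f.min()),
        amplitude=float(f.max() - f.min()) or 1.0,
        c_half=c_half_init,
        width=(c[-1] - c[0]) / 10.0,
    )
    params["width"].set(min=1e-4)
    params["amplitude"].set(min=0.0)
    result = model.fit(f, params, c=c)
    if not result.success:
        raise FitError(f"stability fit did not converge: {result.message}")
    se = result.params["c_half"].stderr
    return StabilityFit(
        c_half=float(result.params["c_half"].value),
        c_half_se=float(se) if se is not None and np.isfinite(se) else 0.0,
        width=float(result.params["width"].value),
        baseline=float(result.params["baseline"].value),
        amplitude=float(result.params["amplitude"].value),
        flagged=flagged,
    )


DEFAULT_STARS = ((0.001, "***"), (0.01, "**"), (0.1, "*"))


def group_significance(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
    star_thresholds: tuple[tuple[float, str], ...] = DEFAULT_STARS,
) -> SignificanceResult:
    """Two-sided two-sample t test with star annotation.

    Welch's test by default (``equal_var=True`` for Student's).  Stars:
    *** p < 0.001, ** p < 0.01, * p < 0.1 (configurable).  Two groups with
    zero variance and equal means give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return SignificanceResult(t=0.0, p=1.0, stars="")
        return SignificanceResult(t=math.inf, p=0.0, stars=star_thresholds[0][1])
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    stars = ""
    for threshold, symbol in sorted(star_thresholds):
        if p < threshold:
            stars = symbol
            break
    return SignificanceResult(t=float(t), p=float(p), stars=stars)
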