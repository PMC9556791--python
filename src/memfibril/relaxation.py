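"""Lipid motional correlation times from 31P relaxation.

Phospholipid headgroup dynamics are probed through the 31P spin-lattice
(T1) and spin-spin (T2) relaxation of the phosphate resonance.  Relaxation
is driven by reorientation of the 31P chemical-shift tensor by two classes
of motion: a fast (nanosecond) component, tau_f, dominated by headgroup
rotation and wobble, and a slow (microsecond) component, tau_s, dominated
by lateral diffusion of lipids around the curved vesicle surface.  An
order parameter S partitions the spectral density between the two.

The full rate expressions are

    R1 = (2/15) w^2 s^2 (1 + eta^2/3) [ S^2 tau_s / (1 + (w tau_s)^2)
                                       + (1-S^2) tau_f / (1 + (w tau_f)^2) ]
    R2 = (1/15) w^2 s^2 (1 + eta^2/3) { [ same bracket as R1 ]
                                       + (4/3) [ S^2 tau_s + (1-S^2) tau_f ] }

with w the 31P Larmor angular frequency (rad/s), s the CSA expressed as a
dimensionless fraction (ppm x 1e-6) and eta the tensor asymmetry.  In the
regime (w tau_f)^2 >> 1 and (w tau_s)^2 >> (w tau_f)^2 the slow-motion
spectral-density terms are negligible and 1 + (w tau_f)^2 ~ (w tau_f)^2,
giving the simplified, analytically invertible system

    R1 = (2/15) s^2 (1 + eta^2/3) (1 - S^2) / tau_f
    R2 = R1/2 + (4/45) w^2 s^2 (1 + eta^2/3) [ S^2 tau_s + (1-S^2) tau_f ]

which this module inverts to obtain tau_f (linear in T1) and then tau_s.
First-order uncertainty propagation uses the constants C1..C4; see
:func:`propagation_constants` for the two derivation conventions shipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from lmfit import Model


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge or is unphysical."""


PPM = 1e-6

#: 31P spin constants for synaptic-membrane phosphate resonances on a
#: 14.1 T spectrometer: Larmor frequency 2*pi*242 MHz, CSA 160 ppm,
#: asymmetry 0.57, order parameter 0.2.
DEFAULT_P31_PARAMS: "SpinSystemParams"


@dataclass(frozen=True)
class SpinSystemParams:
    """Fixed 31P spin-interaction constants entering every rate formula.

    Parameters
    ----------
    larmor_omega : float
        31P Larmor angular frequency, rad/s.
    csa_sigma_ppm : float
        Chemical-shift anisotropy in ppm; used in formulas as the
        dimensionless fraction ``csa_sigma_ppm * 1e-6``.
    eta : float
        CSA tensor asymmetry parameter, in [0, 1].
    order_param : float
        Motional order parameter S, in [0, 1).
    """

    larmor_omega: float
    csa_sigma_ppm: float
    eta: float
    order_param: float

    def __post_init__(self) -> None:
        if self.larmor_omega <= 0:
            raise ValueError("larmor_omega must be positive")
        if self.csa_sigma_ppm <= 0:
            raise ValueError("csa_sigma_ppm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if not 0.0 <= self.order_param < 1.0:
            raise ValueError("order_param must lie in [0, 1)")

    @property
    def csa_fraction(self) -> float:
        """CSA as a dimensionless fraction (ppm x 1e-6)."""
        return self.csa_sigma_ppm * PPM

    @property
    def csa_term(self) -> float:
        """sigma^2 (1 + eta^2 / 3), the CSA prefactor shared by R1 and R2."""
        return self.csa_fraction**2 * (1.0 + self.eta**2 / 3.0)


DEFAULT_P31_PARAMS = SpinSystemParams(
    larmor_omega=2.0 * math.pi * 242e6,
    csa_sigma_ppm=160.0,
    eta=0.57,
    order_param=0.2,
)


@dataclass
class RelaxationSeries:
    """A T1 or T2 relaxation decay/recovery series.

    ``delays`` in seconds, strictly increasing; ``intensities`` are peak
    volumes in arbitrary units (normalization is irrelevant to the decay
    constant).
    """

    kind: Literal["T1", "T2"]
    delays: np.ndarray
    intensities: np.ndarray
    temperature: float = 298.0
    label: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.kind not in ("T1", "T2"):
            raise ValueError("kind must be 'T1' or 'T2'")
        if self.delays.size < 4:
            raise ValueError("need at least 4 delay points")
        if self.delays.size != self.intensities.size:
            raise ValueError("delays and intensities must have equal length")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")


@dataclass
class ExponentialFit:
    """Result of a single-exponential T1/T2 fit; ``rate`` is 1/tau."""

    I0: float
    tau: float
    sigma_tau: float
    rate: float
    residual_rms: float
    kind: Literal["T1", "T2"] = "T2"
    beta: float | None = None  # inversion-recovery amplitude factor (T1 only)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class PropagationConstants:
    """First-order error-propagation constants C1..C4 (see module docs)."""

    C1: float  # s^-2
    C2: float  # s^2
    C3: float  # s^2
    C4: float  # dimensionless
    derivation_mode: Literal["as_printed", "self_consistent"]
    larmor_omega: float

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "C3", "C4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CorrelationResult:
    """Fast/slow correlation times with propagated uncertainties.

    ``validity_metric`` is (omega * tau_f)^2; the simplified inversion is
    trusted when it falls inside the configured window (default [4, 10]).
    """

    tau_f: float
    tau_s: float
    sigma_tau_f: float
    sigma_tau_s: float
    validity_metric: float
    valid: bool
    temperature: float | None = None
    label: str = ""


@dataclass
class DeltaTau:
    """Peptide-induced change of correlation times (sample minus control)."""

    delta_tau_f: float
    delta_tau_s: float
    sigma_delta_f: float
    sigma_delta_s: float
    incubation_label: str = ""


def _t2_model(t, I0, tau):
    return I0 * np.exp(-t / tau)


def _t1_model(t, I0, beta, tau):
    return I0 * (1.0 - beta * np.exp(-t / tau))


def _loglinear_tau_guess(delays: np.ndarray, intensities: np.ndarray) -> float:
    """Deterministic initial tau from a log-linear regression."""
    pos = intensities > 0
    if pos.sum() >= 2:
        slope = np.polyfit(delays[pos], np.log(intensities[pos]), 1)[0]
        if slope < 0:
            return -1.0 / slope
    span = delays[-1] - delays[0]
    return span / 3.0 if span > 0 else 1.0


def fit_exponential_decay(
    series: RelaxationSeries, fix_beta: float | None = None
) -> ExponentialFit:
    """Fit the kind-appropriate exponential model to a relaxation series.

    T2: ``I(t) = I0 exp(-t/tau)``.  T1 (inversion recovery):
    ``I(t) = I0 (1 - beta exp(-t/tau))`` with beta free by default; pass
    ``fix_beta=2.0`` for the ideal full-inversion form.

    Raises
    ------
    FitError
        If the optimizer does not converge or returns a non-positive tau.
    """
    t, y = series.delays, series.intensities
    if series.kind == "T2":
        model = Model(_t2_model)
        params = model.make_params(
            I0=float(np.max(np.abs(y))), tau=_loglinear_tau_guess(t, y)
        )
        params["tau"].set(min=0.0)
    else:
        i_inf = float(y[-1])
        # recovery toward I0; guess tau from where the signal crosses zero
        crossing = t[np.argmin(np.abs(y))]
        tau0 = crossing / math.log(2.0) if crossing > 0 else (t[-1] - t[0]) / 3.0
        model = Model(_t1_model)
        params = model.make_params(I0=i_inf if i_inf != 0 else 1.0, beta=2.0, tau=tau0)
        params["tau"].set(min=0.0)
        if fix_beta is not None:
            params["beta"].set(value=fix_beta, vary=False)

    result = model.fit(y, params, t=t)
    if not result.success:
        raise FitError(f"relaxation fit did not converge: {result.message}")
    tau = float(result.params["tau"].value)
    if tau <= 0 or not np.isfinite(tau):
        raise FitError(f"relaxation fit returned unphysical tau={tau!r}")
    stderr = result.params["tau"].stderr
    sigma_tau = float(stderr) if stderr is not None and np.isfinite(stderr) else 0.0
    rms = float(np.sqrt(np.mean(result.residual**2)))
    beta = float(result.params["beta"].value) if series.kind == "T1" else None
    return ExponentialFit(
        I0=float(result.params["I0"].value),
        tau=tau,
        sigma_tau=sigma_tau,
        rate=1.0 / tau,
        residual_rms=rms,
        kind=series.kind,
        beta=beta,
    )


def full_rate_model(
    tau_f: float, tau_s: float, params: SpinSystemParams = DEFAULT_P31_PARAMS
) -> tuple[float, float]:
    """R1 and R2 from the full two-timescale spectral-density expressions."""
    if tau_f < 0 or tau_s < 0:
        raise ValueError("correlation times must be non-negative")
    w = params.larmor_omega
    s2 = params.order_param**2
    pref = w**2 * params.csa_term
    bracket = s2 * tau_s / (1.0 + (w * tau_s) ** 2) + (1.0 - s2) * tau_f / (
        1.0 + (w * tau_f) ** 2
    )
    secular = (4.0 / 3.0) * (s2 * tau_s + (1.0 - s2) * tau_f)
    r1 = (2.0 / 15.0) * pref * bracket
    r2 = (1.0 / 15.0) * pref * (bracket + secular)
    return r1, r2


def simplified_rate_model(
    tau_f: float, tau_s: float, params: SpinSystemParams = DEFAULT_P31_PARAMS
) -> tuple[float, float]:
    """R1 and R2 from the simplified (invertible) expressions."""
    if tau_f <= 0 or tau_s < 0:
        raise ValueError("tau_f must be positive, tau_s non-negative")
    w = params.larmor_omega
    s2 = params.order_param**2
    r1 = (2.0 / 15.0) * params.csa_term * (1.0 - s2) / tau_f
    r2 = r1 / 2.0 + (4.0 / 45.0) * w**2 * params.csa_term * (
        s2 * tau_s + (1.0 - s2) * tau_f
    )
    return r1, r2


def propagation_constants(
    params: SpinSystemParams = DEFAULT_P31_PARAMS,
    mode: Literal["as_printed", "self_consistent"] = "as_printed",
) -> PropagationConstants:
    """Compute the uncertainty-propagation constants C1..C4.

    Two conventions are shipped because the published C1 omits the
    (1 - S^2) factor that the simplified R1 inversion actually carries:

    - ``as_printed`` (default): C1 = (2/15) w^2 s^2 (1 + eta^2/3), matching
      the published value (8.74e9 s^-2 for the default 31P constants).
    - ``self_consistent``: C1 multiplied by (1 - S^2), i.e. exactly
      d(tau_f)/d(T1) * w^2 of the implemented inversion.

    C2 = 45 / (4 w^2 s^2 (1 + eta^2/3) S^2) in both modes; C3 and C4 are
    obtained by differentiating the implemented inversion
    (C3 = C2/2, C4 = (1-S^2)^2 C1_printed / (w^2 S^2)) in both modes.
    """
    w = params.larmor_omega
    s2 = params.order_param**2
    c1_printed = (2.0 / 15.0) * w**2 * params.csa_term
    c2 = 45.0 / (4.0 * w**2 * params.csa_term * s2)
    c3 = c2 / 2.0
    c4 = (1.0 - s2) ** 2 * (c1_printed / w**2) / s2
    c1 = c1_printed if mode == "as_printed" else c1_printed * (1.0 - s2)
    if mode not in ("as_printed", "self_consistent"):
        raise ValueError(f"unknown mode {mode!r}")
    return PropagationConstants(
        C1=c1, C2=c2, C3=c3, C4=c4, derivation_mode=mode, larmor_omega=w
    )


def propagate_uncertainty(
    t1_fit: ExponentialFit,
    t2_fit: ExponentialFit,
    constants: PropagationConstants,
) -> tuple[float, float]:
    """First-order propagated uncertainties (sigma_tau_f, sigma_tau_s).

    sigma_tau_f = (C1 / w^2) sigma_T1
    sigma_tau_s = sqrt[ (C2/T2^2)^2 sigma_T2^2 + (C3/T1^2 - C4)^2 sigma_T1^2 ]
    """
    t1, t2 = t1_fit.tau, t2_fit.tau
    if t1 <= 0 or t2 <= 0:
        raise ValueError("T1 and T2 must be positive")
    w2 = constants.larmor_omega**2
    sigma_f = (constants.C1 / w2) * t1_fit.sigma_tau
    sigma_s = math.sqrt(
        (constants.C2 / t2**2) ** 2 * t2_fit.sigma_tau**2
        + (constants.C3 / t1**2 - constants.C4) ** 2 * t1_fit.sigma_tau**2
    )
    return sigma_f, sigma_s


def invert_simplified(
    t1_fit: ExponentialFit,
    t2_fit: ExponentialFit,
    params: SpinSystemParams = DEFAULT_P31_PARAMS,
    validity_window: tuple[float, float] = (4.0, 10.0),
    constants_mode: Literal["as_printed", "self_consistent"] = "as_printed",
    temperature: float | None = None,
    label: str = "",
) -> CorrelationResult:
    """Invert measured T1/T2 into (tau_f, tau_s) via the simplified model.

    tau_f is linear in T1 (the Larmor frequency cancels); tau_s follows
    from R2 after subtracting the tau_f contributions.  A negative tau_s
    (R2 smaller than its fast-motion floor) is reported as-is but flagged
    invalid with a warning, never silently suppressed.
    """
    if t2_fit.tau >= t1_fit.tau:
        raise ValueError("T2 must be shorter than T1 (transverse relaxes faster)")
    w = params.larmor_omega
    s2 = params.order_param**2
    a = (2.0 / 15.0) * params.csa_term * (1.0 - s2)  # tau_f = a * T1
    b = (4.0 / 45.0) * w**2 * params.csa_term
    r1, r2 = t1_fit.rate, t2_fit.rate
    tau_f = a * t1_fit.tau
    tau_s = ((r2 - r1 / 2.0) / b - (1.0 - s2) * tau_f) / s2
    metric = (w * tau_f) ** 2
    valid = validity_window[0] <= metric <= validity_window[1]
    if tau_s <= 0:
        warnings.warn(
            "inconsistent relaxation data: inverted tau_s is non-positive "
            f"({tau_s:.3e} s); result flagged invalid",
            stacklevel=2,
        )
        valid = False
    constants = propagation_constants(params, mode=constants_mode)
    sigma_f, sigma_s = propagate_uncertainty(t1_fit, t2_fit, constants)
    return CorrelationResult(
        tau_f=tau_f,
        tau_s=tau_s,
        sigma_tau_f=sigma_f,
        sigma_tau_s=sigma_s,
        validity_metric=metric,
        valid=valid,
        temperature=temperature,
        label=label,
    )


def delta_correlation_times(
    sample: CorrelationResult, control: CorrelationResult, label: str = ""
) -> DeltaTau:
    """Sample-minus-control correlation-time changes, quadrature errors.

    Positive values mean the peptide restricts the motion (longer
    correlation time); negative values mean acceleration.
    """
    if (
        sample.temperature is not None
        and control.temperature is not None
        and sample.temperature != control.temperature
    ):
        raise ValueError(
            f"temperature mismatch: sample at {sample.temperature} K, "
            f"control at {control.temperature} K"
        )
    return DeltaTau(
        delta_tau_f=sample.tau_f - control.tau_f,
        delta_tau_s=sample.tau_s - control.tau_s,
        sigma_delta_f=math.hypot(sample.sigma_tau_f, control.sigma_tau_f),
        sigma_delta_s=math.hypot(sample.sigma_tau_s, control.sigma_tau_s),
        incubation_label=label,
    )
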