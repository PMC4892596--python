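"""Linear-response theory of the chemotactic drift velocity.

In a shallow attractant gradient the mean up-gradient velocity of a
run-and-tumble bacterium is ``v = chi * dc/dx``, where the chemotactic
coefficient is

    chi = (alpha * u**2) / (3 * sigma**2) * Integral_0^inf exp(-sigma t) K(t) dt

with ``u`` the running speed, ``alpha = (1 - <cos phi>) / tau_r`` the
tumbling decorrelation rate, ``sigma = 2 D_rot + alpha`` the total
direction decorrelation rate, and ``K(t)`` the impulse response of the
tumbling bias to a unit concentration impulse.  For the standard bilobed
kernel

    K(t) = K0 * lam * exp(-lam t) * [lam t - (1 - A)/2 * (lam t)**2]

the integral is elementary and

    chi = K0 * u**2 * alpha / (3 sigma**2) * lam**2 (sigma + A lam) / (sigma + lam)**3.

``A`` measures the loss of precise adaptation: the kernel time-integral
equals ``K0 * A``, so ``A = 0`` is the precisely adapted (balanced-lobe)
response.  The bracket is maximized over the memory rate at
``lam* = 2 sigma / (1 - 3 A)``; evaluating the maximized bracket at
``A > 0`` against the adapted optimum quantifies the velocity advantage
of imprecise adaptation.

The module also implements the linear-regime response amplitude

    K0 ∝ a (1 - a) h'(y) (1 - y) / [h(y) (1 - h(y))],   y = a / (a + K)

for Hill-shaped and allosteric motor response curves ``h(y)`` (clockwise
bias versus fractional CheY-P), whose shape decides where along the
kinase-activity axis the amplitude is maximal.

Units: micrometres, seconds, micromolar throughout.  The amplitude from
:func:`response_amplitude` carries an arbitrary proportionality constant
(fixed to 1) and is only meaningful up to shape/argmax statements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple, Union

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "MotilityParams",
    "ResponseKernel",
    "HillMotor",
    "AllostericMotor",
    "MotorModel",
    "PathwayState",
    "kernel_eval",
    "kernel_integral",
    "kernel_laplace",
    "velocity_bracket",
    "chemotactic_coefficient_closed",
    "chemotactic_coefficient_integral",
    "optimal_memory_rate",
    "adaptation_velocity_gain",
    "motor_response",
    "response_amplitude",
    "amplitude_argmax",
]

#: one-sided offset used when evaluating amplitude limits at a = 0 and a = 1
_A_EDGE = 1e-9


@dataclass(frozen=True)
class MotilityParams:
    """Swimming and tumbling parameters of a run-and-tumble swimmer.

    Parameters
    ----------
    u : float
        Running speed (μm/s).
    tau_r : float
        Baseline mean run time (s).
    D_rot : float
        Rotational diffusivity during runs (rad²/s).
    mean_cos_phi : float
        Mean cosine of the tumble scattering angle; 0.3 for E. coli.
    """

    u: float = 15.0
    tau_r: float = 1.15
    D_rot: float = 0.1
    mean_cos_phi: float = 0.3

    def __post_init__(self) -> None:
        if not self.u > 0:
            raise ValueError(f"running speed must be positive, got u={self.u}")
        if not self.tau_r > 0:
            raise ValueError(f"run time must be positive, got tau_r={self.tau_r}")
        if self.D_rot < 0:
            raise ValueError(f"rotational diffusivity must be >= 0, got {self.D_rot}")
        if not -1.0 < self.mean_cos_phi < 1.0:
            raise ValueError(
                f"mean tumble-angle cosine must lie in (-1, 1), got {self.mean_cos_phi}"
            )

    @property
    def alpha(self) -> float:
        """Tumbling decorrelation rate (1/s): (1 - <cos phi>) / tau_r."""
        return (1.0 - self.mean_cos_phi) / self.tau_r

    @property
    def sigma(self) -> float:
        """Total 3-D direction decorrelation rate (1/s): 2 D_rot + alpha."""
        return 2.0 * self.D_rot + self.alpha

    @property
    def diffusivity(self) -> float:
        """Long-time translational diffusivity u² / (3 sigma) (μm²/s)."""
        return self.u**2 / (3.0 * self.sigma)

    def with_run_time(self, tau_r: float) -> "MotilityParams":
        """Copy with a different baseline run time (e.g. locally modulated)."""
        return MotilityParams(self.u, tau_r, self.D_rot, self.mean_cos_phi)


@dataclass(frozen=True)
class ResponseKernel:
    """Bilobed impulse response K(t) = K0 λ e^{-λt} [λt - (1-A)/2 (λt)²].

    ``K0`` (1/μM) sets the sensitivity, ``1/lam`` the memory time and ``A``
    the imbalance between positive and negative lobes; the time integral is
    exactly ``K0 * A``, so A = 0 is precise adaptation.
    """

    K0: float = 1.0
    lam: float = 1.0
    A: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"memory rate must be positive, got lam={self.lam}")
        if not math.isfinite(self.K0):
            raise ValueError("kernel amplitude K0 must be finite")

    def __call__(self, t):
        return kernel_eval(self, t)


def kernel_eval(kernel: ResponseKernel, t):
    """Evaluate the bilobed response kernel at time(s) ``t >= 0`` (1/(μM·s))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal: t must be >= 0")
    lt = kernel.lam * t
    out = kernel.K0 * kernel.lam * np.exp(-lt) * (lt - 0.5 * (1.0 - kernel.A) * lt**2)
    return out if out.ndim else float(out)


def kernel_integral(kernel: ResponseKernel) -> float:
    """Time integral of the kernel by adaptive quadrature (1/μM).

    Equals ``K0 * A`` analytically; a vanishing value means the steady-state
    run bias is insensitive to absolute concentration (precise adaptation).
    """
    upper = 40.0 / kernel.lam
    val, _ = integrate.quad(lambda t: kernel_eval(kernel, t), 0.0, upper,
                            epsabs=1e-12, epsrel=1e-10, limit=200)
    return val


def kernel_laplace(kernel: ResponseKernel, s: float) -> float:
    """Closed-form Laplace transform ∫ e^{-st} K(t) dt = K0 λ² (s + Aλ)/(s + λ)³."""
    return kernel.K0 * kernel.lam**2 * (s + kernel.A * kernel.lam) / (s + kernel.lam) ** 3


def velocity_bracket(lam: float, sigma: float, A: float) -> float:
    """Memory-rate factor λ²(σ + Aλ)/(σ + λ)³ of the closed-form coefficient."""
    return lam**2 * (sigma + A * lam) / (sigma + lam) ** 3


def chemotactic_coefficient_closed(
    motility: MotilityParams, kernel: ResponseKernel
) -> float:
    """Closed-form chemotactic coefficient χ (μm²/(s·μM)) for the bilobed kernel."""
    a, s = motility.alpha, motility.sigma
    return kernel.K0 * motility.u**2 * a / (3.0 * s**2) * velocity_bracket(
        kernel.lam, s, kernel.A
    )


def chemotactic_coefficient_integral(
    motility: MotilityParams, kernel_fn: Callable[[float], float]
) -> float:
    """Chemotactic coefficient by numerical Laplace transform of an arbitrary kernel.

    Computes ``alpha u² / (3 sigma²) * ∫_0^inf e^{-sigma t} K(t) dt`` by
    adaptive quadrature.  Accepts any integrable response ``kernel_fn``, not
    only the bilobed form.

    Raises
    ------
    RuntimeError
        If the quadrature fails to converge; the message carries the
        scipy diagnostics.
    """
    s = motility.sigma
    lam_guess = getattr(kernel_fn, "lam", None)
    upper = 40.0 / min(s, lam_guess) if lam_guess else 40.0 / s
    integrand = lambda t: math.exp(-s * t) * float(kernel_fn(t))
    # split off an early panel so narrow features near t=0 are resolved
    split = min(1.0, upper / 2.0)
    val = abserr = 0.0
    for a, b in ((0.0, split), (split, upper)):
        v, e = integrate.quad(integrand, a, b, epsabs=1e-12, epsrel=1e-10,
                              limit=400)
        val += v
        abserr += e
    if abserr > 1e-6 * max(1.0, abs(val)):
        raise RuntimeError(
            f"kernel quadrature did not converge: value={val}, abserr={abserr}"
        )
    return motility.alpha * motility.u**2 / (3.0 * s**2) * val


def optimal_memory_rate(A: float, sigma: float) -> float:
    """Memory rate λ* = 2σ/(1 - 3A) maximizing the velocity bracket over λ.

    Defined for ``A < 1/3``; the optimum runs off to infinity (pole) as
    ``A -> 1/3``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if A >= 1.0 / 3.0:
        raise ValueError(
            f"optimal memory rate diverges for A >= 1/3 (got A={A}): the "
            "bracket becomes unbounded in lambda"
        )
    return 2.0 * sigma / (1.0 - 3.0 * A)


def adaptation_velocity_gain(A: float, sigma: float = 1.0) -> float:
    """Velocity ratio of the λ-optimized coefficient at ``A`` vs precise adaptation.

    Returns ``g(λ*(A), A) / g(λ*(0), 0)`` with ``g`` the velocity bracket;
    the ratio is independent of ``sigma`` (both brackets scale as 1/σ).
    The excess over 1 is the fractional drift-speed advantage conferred by
    imprecise adaptation when the memory rate is at its optimum.
    """
    if not 0.0 <= A < 1.0 / 3.0:
        raise ValueError(f"gain defined for 0 <= A < 1/3, got A={A}")
    g_a = velocity_bracket(optimal_memory_rate(A, sigma), sigma, A)
    g_0 = velocity_bracket(optimal_memory_rate(0.0, sigma), sigma, 0.0)
    return g_a / g_0


# ---------------------------------------------------------------------------
# Motor response curves and the linear-regime amplitude
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillMotor:
    """Hill-shaped clockwise-bias curve h(y) = [1 + (y/y0)^(-H)]^(-1).

    Vanishes at y = 0: the motor has no basal clockwise switching.
    """

    H: float = 10.0
    y0: float = 0.5

    def __post_init__(self) -> None:
        if not self.H > 0:
            raise ValueError(f"Hill coefficient must be positive, got {self.H}")
        if not 0.0 < self.y0 < 1.0:
            raise ValueError(f"half-max point y0 must lie in (0, 1), got {self.y0}")

    def bias(self, y):
        y = np.asarray(y, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 + (y / self.y0) ** (-self.H))
        out = np.where(y == 0.0, 0.0, out)
        return out if out.ndim else float(out)

    def bias_slope(self, y):
        # h' = H/y * h (1 - h); the log-derivative of h/(1-h) is H/y
        y = np.asarray(y, dtype=float)
        h = self.bias(y)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.H / y * h * (1.0 - h)
        # limit at y=0: H y^(H-1) / y0^H
        at_zero = np.inf if self.H < 1 else (1.0 / self.y0 if self.H == 1 else 0.0)
        out = np.where(y == 0.0, at_zero, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class AllostericMotor:
    """Allosteric (conformational-spread) bias h(y) = 1/[1 + C r(y)^n].

    ``r(y) = (1 + y/K1)/(1 + y/K2)`` with ``K1 > K2 > 0`` so the bias is
    increasing; ``C`` is the basal conformational equilibrium constant and
    ``n`` the number of coupled units.  Unlike the Hill form the bias is
    finite at y = 0 (basal switching rate 1/(1 + C)).
    """

    C: float = 5.0
    n: float = 6.0
    K1: float = 1.0
    K2: float = 0.3

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"equilibrium constant C must be positive, got {self.C}")
        if not self.n > 0:
            raise ValueError(f"number of units n must be positive, got {self.n}")
        if not self.K1 > self.K2 > 0:
            raise ValueError(
                f"dissociation constants must satisfy K1 > K2 > 0, got "
                f"K1={self.K1}, K2={self.K2}"
            )

    def bias(self, y):
        y = np.asarray(y, dtype=float)
        r = (1.0 + y / self.K1) / (1.0 + y / self.K2)
        out = 1.0 / (1.0 + self.C * r**self.n)
        return out if out.ndim else float(out)

    def bias_slope(self, y):
        y = np.asarray(y, dtype=float)
        r = (1.0 + y / self.K1) / (1.0 + y / self.K2)
        # r' = (1/K1 - 1/K2) / (1 + y/K2)^2   (negative since K1 > K2)
        rp = (1.0 / self.K1 - 1.0 / self.K2) / (1.0 + y / self.K2) ** 2
        h = 1.0 / (1.0 + self.C * r**self.n)
        out = -(h**2) * self.C * self.n * r ** (self.n - 1.0) * rp
        return out if out.ndim else float(out)


MotorModel = Union[HillMotor, AllostericMotor]


@dataclass(frozen=True)
class PathwayState:
    """Pathway operating point: fractional CheA-P activity and CheY-P coupling.

    ``a`` is the fractional kinase activity; the fractional CheY-P level
    follows the quasi-steady-state relation ``y = a / (a + K_qss)``.
    """

    a: float
    K_qss: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"fractional activity a must lie in [0, 1], got {self.a}")
        if not self.K_qss > 0:
            raise ValueError(f"quasi-steady constant must be positive, got {self.K_qss}")

    @property
    def y(self) -> float:
        return self.a / (self.a + self.K_qss)


def motor_response(motor: MotorModel, y) -> Tuple[np.ndarray, np.ndarray]:
    """Clockwise bias h(y) and its exact slope h'(y)."""
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("CheY-P fraction y must be >= 0")
    return motor.bias(y), motor.bias_slope(y)


def response_amplitude(state: PathwayState, motor: MotorModel) -> float:
    """Linear-regime response amplitude a(1-a) h'(y)(1-y) / [h(1-h)], y = a/(a+K).

    Arbitrary units (proportionality constant fixed to 1).  The endpoints
    a = 0 and a = 1 are evaluated as one-sided limits a = 1e-9, 1 - 1e-9.
    """
    a = min(max(state.a, _A_EDGE), 1.0 - _A_EDGE)
    y = a / (a + state.K_qss)
    h, hp = motor.bias(y), motor.bias_slope(y)
    denom = h * (1.0 - h)
    if denom == 0.0:
        raise FloatingPointError(
            f"motor bias saturated (h={h}) at y={y}: amplitude undefined; "
            "evaluate away from the saturated branch"
        )
    return a * (1.0 - a) * hp * (1.0 - y) / denom


def amplitude_argmax(motor: MotorModel, K_qss: float = 0.5, n_grid: int = 512) -> float:
    """Kinase activity a* in [0, 1] maximizing the response amplitude.

    Dense-grid prescan followed by bounded local refinement.  For the Hill
    motor the amplitude is H·K·(1-a), decreasing, so a* = 0; allosteric
    motors peak at an interior 0 < a* < 1/2.
    """
    grid = np.linspace(_A_EDGE, 1.0 - _A_EDGE, n_grid)
    vals = np.array([response_amplitude(PathwayState(a, K_qss), motor) for a in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if i == 0:
        # boundary maximum: the amplitude is maximal at zero activity
        res = optimize.minimize_scalar(
            lambda a: -response_amplitude(PathwayState(a, K_qss), motor),
            bounds=(_A_EDGE, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        return 0.0 if res.x <= 2.0 * grid[1] - grid[0] else float(res.x)
    res = optimize.minimize_scalar(
        lambda a: -response_amplitude(PathwayState(a, K_qss), motor),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    return float(res.x)
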