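"""Core kinetic model of amyloid-beta accumulation and bexarotene treatment.

The model tracks four states in the brain of an APP/PS1 mouse:

* ``N``  — healthy brain cells (neurons + glia) per unit volume,
* ``Nd`` — diseased brain cells per unit volume,
* ``A``  — soluble amyloid-beta-42 load (pmol per mg protein),
* ``P0`` — bexarotene-induced, unbound ApoE per unit volume.

Healthy cells convert to diseased cells at a Michaelis–Menten rate driven
by the amyloid load, diseased cells can recover while they have not yet
died (death is an absorbing sink at rate ``mu_d``), diseased cells produce
amyloid, and drug-induced ApoE binds and clears amyloid.  Bexarotene
enters as an exogenous forcing function ``B(t)``: an instantaneous rise to
the dose level at each administration followed by first-order elimination.

All rates are per day; the month/day conversion used throughout the
package is 1 month = 30 days, with the initial conditions anchored at a
mouse age of 2 months (model time t = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "DAYS_PER_MONTH",
    "AGE_AT_START_MONTHS",
    "ModelParameters",
    "InitialConditions",
    "DosingRegimen",
    "SystemState",
    "StateDerivative",
    "disease_rate",
    "recovery_rate",
    "bexarotene_level",
    "system_derivatives",
    "age_months_to_days",
]

#: Month -> day conversion used for mouse ages (a plain convention,
#: configurable where ages are consumed).
DAYS_PER_MONTH: float = 30.0

#: Mouse age (months) at which the default initial conditions hold.
AGE_AT_START_MONTHS: float = 2.0


def age_months_to_days(age_months: float, days_per_month: float = DAYS_PER_MONTH) -> float:
    """Model time (days since t=0) at which a mouse reaches ``age_months``."""
    return (age_months - AGE_AT_START_MONTHS) * days_per_month


def _require_finite_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class ModelParameters:
    """The six lumped rate constants of the reduced system.

    Defaults are the published simulation values.

    Attributes
    ----------
    lambda_d : float
        Maximum healthy->diseased conversion rate, day^-1.
    alpha_d : float
        Half-saturation amyloid load of the conversion rate, pmol mg^-1.
    mu_d : float
        Diseased-cell death rate, day^-1.
    k_A : float
        Amyloid production constant, pmol (mg day vol^2)^-1.
    k_P0 : float
        ApoE–amyloid binding/removal rate, vol day^-1.
    k_B : float
        Lumped bexarotene->ApoE production rate, kg mg^-1 day^-1.
    """

    lambda_d: float = 6.1e-2
    alpha_d: float = 17.0
    mu_d: float = 5e-3
    k_A: float = 3.5e-4
    k_P0: float = 4.4e-2
    k_B: float = 5e-2

    def __post_init__(self) -> None:
        for name in ("lambda_d", "alpha_d", "mu_d", "k_A", "k_P0", "k_B"):
            _require_finite_positive(name, getattr(self, name))

    def replace(self, **changes: float) -> "ModelParameters":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class InitialConditions:
    """State of the system at model time zero (mouse age 2 months)."""

    N0: float = 100.0
    Nd0: float = 0.0
    A0: float = 0.25
    P00: float = 0.0
    age0_days: float = AGE_AT_START_MONTHS * DAYS_PER_MONTH

    def __post_init__(self) -> None:
        for name in ("N0", "Nd0", "A0", "P00"):
            _require_finite_nonneg(name, getattr(self, name))
        _require_finite_nonneg("age0_days", self.age0_days)

    def as_state(self) -> "SystemState":
        return SystemState(N=self.N0, Nd=self.Nd0, A=self.A0, P0=self.P00)


DoseMode = Literal["pulsed", "constant", "none"]


@dataclass(frozen=True)
class DosingRegimen:
    """Bexarotene administration schedule.

    ``pulsed`` mode resets the drug concentration to ``B0`` at every dose
    time ``t_B + n L`` and lets it decay exponentially at the elimination
    rate ``r`` in between; ``constant`` holds the level at ``B0`` from
    ``t_B`` onward; ``none`` is the untreated null regimen.
    """

    B0: float = 0.0
    t_B: float = 0.0
    L: float = 1.0
    r: float = 15.26
    mode: DoseMode = "pulsed"

    def __post_init__(self) -> None:
        _require_finite_nonneg("B0", self.B0)
        _require_finite_nonneg("t_B", self.t_B)
        _require_finite_positive("r", self.r)
        if self.mode not in ("pulsed", "constant", "none"):
            raise ValueError(f"mode must be pulsed/constant/none, got {self.mode!r}")
        if self.mode == "pulsed" and not (math.isfinite(self.L) and self.L > 0):
            raise ValueError(f"L must be > 0 in pulsed mode, got {self.L!r}")

    @classmethod
    def untreated(cls) -> "DosingRegimen":
        return cls(B0=0.0, mode="none")

    def dose_times(self, duration: float) -> list[float]:
        """Administration instants in [0, duration) (empty for none/constant-before-start)."""
        if self.mode == "none" or self.B0 == 0.0:
            return []
        if self.mode == "constant":
            return [self.t_B] if 0.0 <= self.t_B < duration else []
        times = []
        n = 0
        while (t := self.t_B + n * self.L) < duration:
            times.append(t)
            n += 1
        return times


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state (N, Nd, A, P0); all components non-negative."""

    N: float
    Nd: float
    A: float
    P0: float

    def __post_init__(self) -> None:
        for name in ("N", "Nd", "A", "P0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    def as_array(self):
        import numpy as np

        return np.array([self.N, self.Nd, self.A, self.P0], dtype=float)


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of a SystemState, per day.

    Satisfies dN + dNd = -mu_d * Nd exactly: cell conversion is
    conservative and only diseased-cell death removes cells.
    """

    dN: float
    dNd: float
    dA: float
    dP0: float


def disease_rate(A: float, params: ModelParameters) -> float:
    """Healthy->diseased conversion rate k_d(A) = lambda_d * A / (A + alpha_d).

    Michaelis–Menten in the amyloid load: zero at A=0, half-maximal at
    A = alpha_d, saturating at lambda_d.
    """
    if A < 0:
        raise ValueError(f"amyloid load A must be non-negative, got {A!r}")
    return params.lambda_d * A / (A + params.alpha_d)


def recovery_rate(A: float, params: ModelParameters) -> float:
    """Diseased->healthy recovery rate k_h(A) = lambda_d - k_d(A)."""
    return params.lambda_d - disease_rate(A, params)


def bexarotene_level(t: float, regimen: DosingRegimen) -> float:
    """Drug concentration B(t) (mg/kg) at model time ``t`` (days).

    Pulsed mode: B(t) = B0 * exp(r L (floor(s) - s)) with s = (t - t_B)/L
    for t >= t_B, zero before; exactly periodic with period L after t_B.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t!r}")
    if regimen.mode == "none" or regimen.B0 == 0.0:
        return 0.0
    if t < regimen.t_B:
        return 0.0
    if regimen.mode == "constant":
        return regimen.B0
    s = (t - regimen.t_B) / regimen.L
    return regimen.B0 * math.exp(regimen.r * regimen.L * (math.floor(s) - s))


def _rhs(N: float, Nd: float, A: float, P0: float, B: float, p: ModelParameters):
    """Raw right-hand side on plain floats (hot path for integrators)."""
    kd = p.lambda_d * A / (A + p.alpha_d)
    kh = p.lambda_d - kd
    removal = p.k_P0 * A * P0
    dN = -kd * N + kh * Nd
    dNd = kd * N - kh * Nd - p.mu_d * Nd
    dA = p.k_A * (Nd * Nd + Nd * N) - removal
    dP0 = p.k_B * N * B - removal
    return dN, dNd, dA, dP0


def system_derivatives(
    t: float,
    state: SystemState,
    params: ModelParameters,
    regimen: DosingRegimen,
) -> StateDerivative:
    """Full right-hand side of the four-state ODE system at time ``t``."""
    B = bexarotene_level(t, regimen)
    dN, dNd, dA, dP0 = _rhs(state.N, state.Nd, state.A, state.P0, B, params)
    for name, v in (("dN", dN), ("dNd", dNd), ("dA", dA), ("dP0", dP0)):
        if not math.isfinite(v):
            raise ArithmeticError(f"non-finite derivative {name}={v!r} at t={t}")
    return StateDerivative(dN=dN, dNd=dNd, dA=dA, dP0=dP0)
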