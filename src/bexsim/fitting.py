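"""Two-stage least-squares calibration of the disease model.

Stage 1 fits the disease-progression parameters {lambda_d, alpha_d,
mu_d, k_A} to an untreated amyloid-load time course; stage 2, with the
stage-1 values frozen, fits the treatment parameters {k_P0, k_B} to
percent-decrease-in-soluble-amyloid endpoints of treated-versus-
untreated protocols.  Both stages minimize a plain sum of squared
differences, exploring the parameter space with a deterministic
log-spaced grid scan followed by derivative-free local refinement
(Nelder–Mead) from the best grid point.

The half-saturation constant alpha_d is fittable by default but can be
frozen (``freeze_alpha=True``), mirroring a calibration style where it
is pinned a priori to reproduce the observed lag before the rapid rise
of the amyloid curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import DosingRegimen, InitialConditions, ModelParameters, age_months_to_days
from .simulate import (
    IntegrationError,
    _solve_segment,
    final_state,
    untreated_state_at,
)

__all__ = [
    "AbetaObservation",
    "TreatmentObservation",
    "FitResult",
    "STAGE1_NAMES",
    "STAGE2_NAMES",
    "objective_untreated",
    "fit_untreated",
    "objective_treatment",
    "fit_treatment",
    "read_abeta_csv",
    "write_abeta_csv",
    "read_treatment_csv",
    "write_treatment_csv",
]

STAGE1_NAMES = ("lambda_d", "alpha_d", "mu_d", "k_A")
STAGE2_NAMES = ("k_P0", "k_B")

#: Objective value returned (with a warning) when integration fails,
#: so grid scans and simplex searches survive pathological corners.
PENALTY_SSE = 1e12

#: Default fitting-stage solver tolerances (looser than simulation
#: defaults: the objective is evaluated thousands of times).
FIT_RTOL = 1e-6
FIT_ATOL = 1e-8


@dataclass(frozen=True)
class AbetaObservation:
    """One amyloid-load measurement of an untreated mouse."""

    t: float  # days since age 2 months
    A_obs: float  # pmol/mg

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"observation time must be >= 0, got {self.t}")
        if self.A_obs < 0:
            raise ValueError(f"amyloid load must be >= 0, got {self.A_obs}")


@dataclass(frozen=True)
class TreatmentObservation:
    """Observed fractional decrease in soluble amyloid for one protocol."""

    age_months: float
    days_treated: float
    B0: float = 100.0
    L: float = 1.0
    pct_decrease_obs: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_decrease_obs <= 1.0:
            raise ValueError(
                f"pct_decrease_obs must be in [0, 1], got {self.pct_decrease_obs}"
            )


@dataclass
class FitResult:
    """Outcome of one fitting stage."""

    params: ModelParameters
    sse: float
    n_evals: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def _simulate_A_at(
    params: ModelParameters,
    ics: InitialConditions,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Untreated amyloid load at the requested times (single solve)."""
    t_end = float(times.max())
    y0 = ics.as_state().as_array()
    if t_end == 0.0:
        return np.full(times.shape, ics.A0)
    sol = _solve_segment(
        params, y0, 0.0, t_end, lambda t: 0.0, np.unique(np.concatenate([[0.0], times])),
        rtol, atol, "LSODA",
    )
    lookup = dict(zip(sol.t, sol.y[2]))
    return np.array([lookup[t] for t in times])


def objective_untreated(
    theta: Mapping[str, float],
    obs: Sequence[AbetaObservation],
    fixed: InitialConditions | None = None,
    base_params: ModelParameters | None = None,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> float:
    """Sum of squared amyloid-load residuals of an untreated simulation.

    ``theta`` supplies any subset of {lambda_d, alpha_d, mu_d, k_A};
    remaining parameters come from ``base_params``.  The treatment
    parameters are irrelevant here (no drug, no induced ApoE).
    """
    if any(v <= 0 for v in theta.values()):
        raise ValueError(f"stage-1 parameters must be strictly positive, got {dict(theta)}")
    unknown = set(theta) - set(STAGE1_NAMES)
    if unknown:
        raise ValueError(f"unexpected stage-1 parameters {sorted(unknown)}")
    fixed = fixed or InitialConditions()
    base = base_params or ModelParameters()
    params = base.replace(**dict(theta))
    times = np.array([o.t for o in obs], dtype=float)
    target = np.array([o.A_obs for o in obs], dtype=float)
    try:
        model = _simulate_A_at(params, fixed, times, rtol, atol)
    except (IntegrationError, ArithmeticError) as exc:
        warnings.warn(f"integration failed for theta={dict(theta)}: {exc}; penalizing")
        return PENALTY_SSE
    return float(np.sum((model - target) ** 2))


def _log_grid(bounds: Mapping[str, tuple[float, float]], points_per_decade: int = 8):
    """Deterministic log-spaced axes, >= points_per_decade per decade."""
    axes = {}
    for name, (lo, hi) in bounds.items():
        if not (0 < lo < hi):
            raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi")
        decades = math.log10(hi / lo)
        n = max(2, int(math.ceil(points_per_decade * decades)) + 1)
        axes[name] = np.logspace(math.log10(lo), math.log10(hi), n)
    return axes


def _grid_then_refine(objective, names, bounds, points_per_decade, refine_opts):
    axes = _log_grid({n: bounds[n] for n in names}, points_per_decade)
    mesh = np.meshgrid(*[axes[n] for n in names], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    n_evals = 0
    best_sse, best_x = np.inf, None
    for x in pts:
        sse = objective(dict(zip(names, x)))
        n_evals += 1
        if sse < best_sse:
            best_sse, best_x = sse, x
    if best_x is None or best_sse >= PENALTY_SSE:
        raise RuntimeError("every grid point was penalized; fit failed")

    # Nelder–Mead in log-space keeps positivity and scales uniformly.
    def f_log(z):
        x = np.exp(z)
        if np.any(x < np.array([bounds[n][0] for n in names]) * 0.5) or np.any(
            x > np.array([bounds[n][1] for n in names]) * 2.0
        ):
            return PENALTY_SSE
        return objective(dict(zip(names, x)))

    opts = {"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000, **(refine_opts or {})}
    res = minimize(f_log, np.log(best_x), method="Nelder-Mead", options=opts)
    n_evals += res.nfev
    x_hat = np.exp(res.x)
    sse_hat = float(res.fun)
    if sse_hat > best_sse:  # refinement should never regress
        x_hat, sse_hat = best_x, best_sse
    return dict(zip(names, (float(v) for v in x_hat))), sse_hat, n_evals, bool(res.success)


def fit_untreated(
    obs: Sequence[AbetaObservation],
    init: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    *,
    fixed: InitialConditions | None = None,
    base_params: ModelParameters | None = None,
    freeze_alpha: bool = False,
    points_per_decade: int = 8,
    refine_opts: dict | None = None,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Stage-1 fit of {lambda_d, alpha_d, mu_d, k_A} to an amyloid time course.

    Deterministic: a log-spaced grid scan over ``bounds`` (default:
    a factor of two either side of ``init``), then Nelder–Mead from the
    best grid point.  Requires at least 4 observations spanning the
    rise of the sigmoid.
    """
    if len(obs) < 4:
        raise ValueError(f"need >= 4 observations to fit 4 parameters, got {len(obs)}")
    base = base_params or ModelParameters()
    init = dict(init) if init else {n: getattr(base, n) for n in STAGE1_NAMES}
    names = tuple(n for n in STAGE1_NAMES if not (freeze_alpha and n == "alpha_d"))
    if bounds is None:
        bounds = {n: (init[n] / 2.0, init[n] * 2.0) for n in names}

    frozen = {} if not freeze_alpha else {"alpha_d": init.get("alpha_d", base.alpha_d)}

    def obj(theta: Mapping[str, float]) -> float:
        return objective_untreated(
            {**frozen, **theta}, obs, fixed=fixed, base_params=base, rtol=rtol, atol=atol
        )

    theta_hat, sse, n_evals, ok = _grid_then_refine(obj, names, bounds, points_per_decade, refine_opts)
    params = base.replace(**{**frozen, **theta_hat})
    return FitResult(params=params, sse=sse, n_evals=n_evals, converged=ok)


# ---------------------------------------------------------------------------
# Stage 2: treatment parameters against percent-decrease endpoints
# ---------------------------------------------------------------------------

def _simulated_pct_decrease(
    params: ModelParameters,
    ics: InitialConditions,
    cond: TreatmentObservation,
    rtol: float,
    atol: float,
) -> float:
    t_B = age_months_to_days(cond.age_months)
    t_f = t_B + cond.days_treated
    a_untreated = untreated_state_at(params, ics, t_f, rtol, atol).A
    regimen = DosingRegimen(B0=cond.B0, t_B=t_B, L=cond.L, mode="pulsed")
    a_treated = final_state(params, ics, regimen, t_f, rtol, atol).A
    if a_untreated == 0:
        raise ZeroDivisionError("untreated amyloid endpoint is zero")
    return (a_untreated - a_treated) / a_untreated


def objective_treatment(
    phi: Mapping[str, float],
    obs: Sequence[TreatmentObservation],
    stage1: ModelParameters,
    fixed: InitialConditions | None = None,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> float:
    """SSE between simulated and observed fractional amyloid decreases.

    ``phi`` supplies {k_P0, k_B}; every other parameter is frozen at the
    stage-1 values.  Each observation costs a treated life course; the
    untreated arms depend only on stage-1 parameters and are served from
    the burn-in cache.
    """
    if any(v <= 0 for v in phi.values()):
        raise ValueError(f"stage-2 parameters must be strictly positive, got {dict(phi)}")
    unknown = set(phi) - set(STAGE2_NAMES)
    if unknown:
        raise ValueError(f"unexpected stage-2 parameters {sorted(unknown)}")
    fixed = fixed or InitialConditions()
    params = stage1.replace(**dict(phi))
    sse = 0.0
    for cond in obs:
        try:
            delta = _simulated_pct_decrease(params, fixed, cond, rtol, atol)
        except (IntegrationError, ArithmeticError, ZeroDivisionError) as exc:
            warnings.warn(f"integration failed for phi={dict(phi)}: {exc}; penalizing")
            return PENALTY_SSE
        sse += (delta - cond.pct_decrease_obs) ** 2
    return float(sse)


def fit_treatment(
    obs: Sequence[TreatmentObservation],
    init: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    stage1: ModelParameters | None = None,
    *,
    fixed: InitialConditions | None = None,
    points_per_decade: int = 8,
    refine_opts: dict | None = None,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Stage-2 fit of {k_P0, k_B}; stage-1 parameters are never re-opened."""
    if len(obs) == 0:
        raise ValueError("need at least one treatment observation")
    stage1 = stage1 or ModelParameters()
    init = dict(init) if init else {n: getattr(stage1, n) for n in STAGE2_NAMES}
    if bounds is None:
        bounds = {n: (init[n] / 2.0, init[n] * 2.0) for n in STAGE2_NAMES}

    def obj(phi: Mapping[str, float]) -> float:
        return objective_treatment(phi, obs, stage1, fixed=fixed, rtol=rtol, atol=atol)

    phi_hat, sse, n_evals, ok = _grid_then_refine(
        obj, STAGE2_NAMES, bounds, points_per_decade, refine_opts
    )
    message = ""
    if len(obs) < len(STAGE2_NAMES):
        message = "under-determined: fewer observations than free parameters"
    params = stage1.replace(**phi_hat)
    return FitResult(params=params, sse=sse, n_evals=n_evals, converged=ok, message=message)


# ---------------------------------------------------------------------------
# Delimited-text dataset I/O
# ---------------------------------------------------------------------------

def read_abeta_csv(path: str | Path) -> list[AbetaObservation]:
    """Read (t_days, A_obs) rows."""
    df = pd.read_csv(path)
    return [AbetaObservation(t=row.t_days, A_obs=row.A_obs) for row in df.itertuples()]


def write_abeta_csv(obs: Sequence[AbetaObservation], path: str | Path) -> None:
    pd.DataFrame({"t_days": [o.t for o in obs], "A_obs": [o.A_obs for o in obs]}).to_csv(
        path, index=False
    )


def read_treatment_csv(path: str | Path) -> list[TreatmentObservation]:
    """Read (age_months, days_treated, B0, L, pct_decrease_obs) rows."""
    df = pd.read_csv(path)
    return [
        TreatmentObservation(
            age_months=row.age_months,
            days_treated=row.days_treated,
            B0=row.B0,
            L=row.L,
            pct_decrease_obs=row.pct_decrease_obs,
        )
        for row in df.itertuples()
    ]


def write_treatment_csv(obs: Sequence[TreatmentObservation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "age_months": [o.age_months for o in obs],
            "days_treated": [o.days_treated for o in obs],
            "B0": [o.B0 for o in obs],
            "L": [o.L for o in obs],
            "pct_decrease_obs": [o.pct_decrease_obs for o in obs],
        }
    ).to_csv(path, index=False)


def fit_result_to_json(result: FitResult, path: str | Path) -> None:
    """Serialize a FitResult to JSON."""
    import json

    payload = {
        "params": {
            "lambda_d": result.params.lambda_d,
            "alpha_d": result.params.alpha_d,
            "mu_d": result.params.mu_d,
            "k_A": result.params.k_A,
            "k_P0": result.params.k_P0,
            "k_B": result.params.k_B,
        },
        "sse": result.sse,
        "n_evals": result.n_evals,
        "converged": result.converged,
        "message": result.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
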