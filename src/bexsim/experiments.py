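"""In-silico treatment experiments on the disease model.

Covers the endpoint percent-change metrics, dose x frequency response
sweeps, the age-dependent critical-dosage search, cross-frequency dose
equivalence, and a one-at-a-time +10% parameter sensitivity table.

Critical dosage
---------------
The dose–response curve of final healthy-cell concentration versus dose
is sigmoidal, and "the dose required to recover healthy brain cells" can
be read off it in more than one defensible way.  Three criteria are
implemented:

``net_recovery`` (default)
    Smallest dose at which the healthy-cell count at the end of the
    treatment window is no lower than at its start — net non-loss of N
    over the window.  Parameter-free.
``elbow``
    The visual knee of the dose–response curve drawn with the sweep's
    natural axis scales (N in [0, N0] cells against dose in
    [0, max_dose] mg/kg): the dose maximizing N_f(B) - (N0/max_dose)·B,
    i.e. where the marginal benefit dN_f/dB falls to N0/max_dose cells
    per mg/kg (0.1 for the default 100-cell, 0–1000 mg/kg sweep).  This
    is the reading that reproduces the published age-dependent critical
    dosages; see docs/methods.md.
``steepest_slope``
    The dose of maximum slope of the dose–response curve (its
    inflection).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DosingRegimen,
    InitialConditions,
    ModelParameters,
    age_months_to_days,
)
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    Trajectory,
    final_state,
    untreated_state_at,
)

__all__ = [
    "MODE_PERIODS",
    "SweepResult",
    "SensitivityRecord",
    "percent_decrease_abeta",
    "percent_increase_cells",
    "treatment_endpoint_states",
    "dose_frequency_sweep",
    "critical_dose",
    "equivalent_dose",
    "sensitivity_table",
    "default_dose_grid",
]

#: Dosing frequency names -> inter-dose period in days (None = constant).
MODE_PERIODS: dict[str, float | None] = {
    "constant": None,
    "daily": 1.0,
    "alternate-day": 2.0,
    "weekly": 7.0,
}


@dataclass
class SweepResult:
    """Final healthy-cell concentration over a (dose, mode) grid."""

    table: pd.DataFrame  # columns: dose, mode, final_N
    meta: dict

    def final_N(self, dose: float, mode: str) -> float:
        t = self.table
        row = t[(t["mode"] == mode) & (np.isclose(t["dose"], dose))]
        if row.empty:
            raise KeyError(f"no sweep cell for dose={dose}, mode={mode}")
        return float(row["final_N"].iloc[0])


@dataclass(frozen=True)
class SensitivityRecord:
    """Percent change of final N under a one-parameter perturbation."""

    parameter: str
    perturbation: float
    dose: float
    pct_change_N: float


def percent_decrease_abeta(traj_untreated: Trajectory, traj_treated: Trajectory) -> float:
    """Fractional decrease in final amyloid load under treatment.

    (A_untreated(t_f) - A_treated(t_f)) / A_untreated(t_f), evaluated at
    the shared end time; depends only on the endpoint states.
    """
    _check_shared_end(traj_untreated, traj_treated)
    a0 = traj_untreated.A[-1]
    if a0 == 0:
        raise ZeroDivisionError("untreated final amyloid load is zero; percent change undefined")
    return float((a0 - traj_treated.A[-1]) / a0)


def percent_increase_cells(traj_untreated: Trajectory, traj_treated: Trajectory) -> float:
    """Fractional increase in final healthy-cell concentration under treatment."""
    _check_shared_end(traj_untreated, traj_treated)
    n0 = traj_untreated.N[-1]
    if n0 == 0:
        raise ZeroDivisionError("untreated final healthy-cell count is zero; percent change undefined")
    return float((traj_treated.N[-1] - n0) / n0)


def _check_shared_end(a: Trajectory, b: Trajectory) -> None:
    if not np.isclose(a.t_final, b.t_final, rtol=0, atol=1e-9):
        raise ValueError(
            f"trajectories must share the same end time, got {a.t_final} vs {b.t_final}"
        )


def _regimen_for(mode: str, B0: float, t_B: float, r: float = 15.26) -> DosingRegimen:
    if B0 == 0.0:
        return DosingRegimen(B0=0.0, t_B=t_B, r=r, mode="none")
    period = MODE_PERIODS[mode]
    if period is None:
        return DosingRegimen(B0=B0, t_B=t_B, r=r, mode="constant")
    return DosingRegimen(B0=B0, t_B=t_B, L=period, r=r, mode="pulsed")


def _final_N(
    params: ModelParameters,
    ics: InitialConditions,
    age_months: float,
    duration_days: float,
    B0: float,
    mode: str,
    rtol: float,
    atol: float,
) -> float:
    t_B = age_months_to_days(age_months)
    regimen = _regimen_for(mode, B0, t_B)
    return final_state(params, ics, regimen, t_B + duration_days, rtol, atol).N


def treatment_endpoint_states(
    params: ModelParameters,
    ics: InitialConditions,
    age_months: float,
    duration_days: float,
    B0: float,
    L: float = 1.0,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
):
    """Endpoint states of the untreated and treated twins of one protocol.

    Returns (untreated_state, treated_state) at t_f = treatment start +
    duration; the untreated twin reuses the cached burn-in solve.
    """
    t_B = age_months_to_days(age_months)
    t_f = t_B + duration_days
    untreated = untreated_state_at(params, ics, t_f, rtol, atol)
    regimen = DosingRegimen(B0=B0, t_B=t_B, L=L, mode="pulsed" if B0 > 0 else "none")
    treated = final_state(params, ics, regimen, t_f, rtol, atol)
    return untreated, treated


def default_dose_grid(max_dose: float = 1000.0, n: int = 101) -> np.ndarray:
    """0 plus ``n`` log-spaced doses over (max_dose/1000, max_dose]."""
    return np.concatenate([[0.0], np.logspace(np.log10(max_dose) - 3, np.log10(max_dose), n)])


def dose_frequency_sweep(
    params: ModelParameters,
    age_months: float,
    duration_days: float,
    doses: Sequence[float] | None = None,
    modes: Sequence[str] = ("constant", "daily", "alternate-day", "weekly"),
    *,
    ics: InitialConditions | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SweepResult:
    """Final N(t_f) for every (dose, mode) cell of the grid."""
    ics = ics or InitialConditions()
    doses = default_dose_grid() if doses is None else np.asarray(doses, dtype=float)
    if not np.any(doses == 0.0):
        raise ValueError("dose grid must include 0 (the untreated reference)")
    unknown = [m for m in modes if m not in MODE_PERIODS]
    if unknown:
        raise ValueError(f"unknown modes {unknown}; choose from {sorted(MODE_PERIODS)}")
    rows = []
    for mode in modes:
        for dose in doses:
            n_f = _final_N(params, ics, age_months, duration_days, float(dose), mode, rtol, atol)
            rows.append({"dose": float(dose), "mode": mode, "final_N": n_f})
    table = pd.DataFrame(rows)
    meta = {
        "age_months": age_months,
        "duration_days": duration_days,
        "params": params,
        "n_doses": len(doses),
    }
    return SweepResult(table=table, meta=meta)


def critical_dose(
    params: ModelParameters,
    age_months: float,
    duration_days: float = 14.0,
    mode: str = "daily",
    dose_bounds: tuple[float, float] = (0.0, 1000.0),
    criterion: str = "net_recovery",
    resolution: float = 1.0,
    *,
    ics: InitialConditions | None = None,
    n_scale: float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float | None:
    """Threshold dose (mg/kg) for recovery of healthy brain cells.

    Located by bisection to ``resolution`` mg/kg under the chosen
    ``criterion`` (see module docstring).  Returns None when the
    criterion is never met within ``dose_bounds`` — the situation of old
    mice, where no dose recovers cells.
    """
    ics = ics or InitialConditions()
    lo, hi = dose_bounds
    if not 0 <= lo < hi:
        raise ValueError("dose_bounds must satisfy 0 <= lo < hi")

    def N_f(B0: float) -> float:
        return _final_N(params, ics, age_months, duration_days, B0, mode, rtol, atol)

    if criterion == "net_recovery":
        n_start = untreated_state_at(params, ics, age_months_to_days(age_months), rtol, atol).N
        # equality up to solver precision counts as recovery
        guard = max(1e-9 * n_start, 10.0 * atol)

        def ok(B0: float) -> bool:
            return N_f(B0) >= n_start - guard

        if ok(lo):
            return float(lo)
        if not ok(hi):
            return None
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if ok(mid):
                hi = mid
            else:
                lo = mid
        return float(hi)

    if criterion in ("elbow", "steepest_slope"):
        scale = (n_scale or ics.N0) / (hi - lo)  # axis aspect: cells per mg/kg
        h = max(resolution, (hi - lo) / 1000.0)

        def slope(B0: float) -> float:
            a = max(B0 - h, lo)
            b = min(B0 + h, hi)
            return (N_f(b) - N_f(a)) / (b - a)

        scan = np.linspace(lo, hi, 41)
        slopes = [slope(b) for b in scan]
        i_max = int(np.argmax(slopes))
        if criterion == "steepest_slope":
            a = scan[max(i_max - 1, 0)]
            b = scan[min(i_max + 1, len(scan) - 1)]
            # golden-section refinement of the slope maximum
            gr = (np.sqrt(5) - 1) / 2
            c, d = b - gr * (b - a), a + gr * (b - a)
            while b - a > resolution:
                if slope(c) > slope(d):
                    b, d = d, c
                    c = b - gr * (b - a)
                else:
                    a, c = c, d
                    d = a + gr * (b - a)
            return float(0.5 * (a + b))
        # elbow: descending crossing of the axis-aspect slope after the max
        if slopes[i_max] < scale:
            return None
        if slope(hi) >= scale:
            return None
        a, b = scan[i_max], hi
        while b - a > resolution:
            mid = 0.5 * (a + b)
            if slope(mid) >= scale:
                a = mid
            else:
                b = mid
        return float(0.5 * (a + b))

    raise ValueError(f"unknown criterion {criterion!r}")


def equivalent_dose(
    params: ModelParameters,
    age_months: float,
    duration_days: float,
    reference: DosingRegimen,
    target_mode: str,
    dose_bounds: tuple[float, float] = (0.0, 5000.0),
    resolution: float = 0.1,
    *,
    ics: InitialConditions | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float | None:
    """Dose in ``target_mode`` matching the reference regimen's final N.

    Bisection on the (monotone, verified on the bracket) dose–response
    of the target mode; returns None if the bracket does not contain the
    reference response.
    """
    ics = ics or InitialConditions()
    t_B = age_months_to_days(age_months)
    t_f = t_B + duration_days
    ref = replace(reference, t_B=t_B)
    n_ref = final_state(params, ics, ref, t_f, rtol, atol).N

    def N_f(B0: float) -> float:
        return _final_N(params, ics, age_months, duration_days, B0, target_mode, rtol, atol)

    lo, hi = dose_bounds
    n_lo, n_hi = N_f(lo), N_f(hi)
    if not (n_lo <= n_ref <= n_hi):
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if N_f(mid) >= n_ref:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def sensitivity_table(
    params: ModelParameters,
    perturbation: float = 0.10,
    age_months: float = 9.0,
    duration_days: float = 90.0,
    doses: Iterable[float] = (0.0, 100.0),
    *,
    ics: InitialConditions | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> list[SensitivityRecord]:
    """One-at-a-time parameter sensitivity of final healthy-cell count.

    Each of the six rate constants is increased by ``perturbation``
    (default +10%) and the percent change of final N relative to the
    unperturbed solve is recorded, for each scenario dose (daily
    administration).
    """
    ics = ics or InitialConditions()
    names = ("lambda_d", "alpha_d", "mu_d", "k_A", "k_P0", "k_B")
    records: list[SensitivityRecord] = []
    for dose in doses:
        base = _final_N(params, ics, age_months, duration_days, float(dose), "daily", rtol, atol)
        for name in names:
            if perturbation == 0.0:
                records.append(SensitivityRecord(name, 0.0, float(dose), 0.0))
                continue
            pert = params.replace(**{name: getattr(params, name) * (1.0 + perturbation)})
            n_f = _final_N(pert, ics, age_months, duration_days, float(dose), "daily", rtol, atol)
            records.append(
                SensitivityRecord(
                    parameter=name,
                    perturbation=perturbation,
                    dose=float(dose),
                    pct_change_N=float(100.0 * (n_f - base) / base),
                )
            )
    return records


def sensitivity_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    """Tidy one-row-per-record table of a sensitivity analysis."""
    return pd.DataFrame(
        [
            {
                "parameter": rec.parameter,
                "perturbation": rec.perturbation,
                "dose": rec.dose,
                "pct_change_N": rec.pct_change_N,
            }
            for rec in records
        ]
    )
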