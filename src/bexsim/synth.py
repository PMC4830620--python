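"""Synthetic datasets with the statistical structure the fitting assumes.

The original calibration data — a longitudinal amyloid-load curve in
untreated APP/PS1 mice and percent-decrease-in-soluble-amyloid endpoints
for treated cohorts — are published only as figures.  This module
generates stand-in datasets from the model itself: a noiseless forward
solve plus additive Gaussian observation noise truncated at the domain
boundary.  With the default generating parameters the noiseless amyloid
curve is sigmoidal with a lag of roughly 3.5 months before its rapid
rise, matching the qualitative shape of the source data.

Noise is observation-level only; the underlying dynamics are
deterministic, which is the implicit error model of a least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .fitting import (
    AbetaObservation,
    TreatmentObservation,
    _simulate_A_at,
    _simulated_pct_decrease,
    write_abeta_csv,
    write_treatment_csv,
)
from .model import DAYS_PER_MONTH, InitialConditions, ModelParameters
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL

__all__ = [
    "SynthSpec",
    "DEFAULT_ENDPOINT_CONDITIONS",
    "generate_abeta_observations",
    "generate_treatment_endpoints",
    "write_fixtures",
]

#: Treatment protocols emulating the published endpoints: 100 mg/kg daily
#: at 6 months for 3/7/14 days, 9 months for 90 days, 11 months for 7 days.
DEFAULT_ENDPOINT_CONDITIONS: tuple[tuple[float, float, float, float], ...] = (
    (6.0, 3.0, 100.0, 1.0),
    (6.0, 7.0, 100.0, 1.0),
    (6.0, 14.0, 100.0, 1.0),
    (9.0, 90.0, 100.0, 1.0),
    (11.0, 7.0, 100.0, 1.0),
)


def _default_abeta_times() -> tuple[float, ...]:
    # monthly sampling from age 2 to 15 months (model time 0..390 d)
    return tuple(float(m * DAYS_PER_MONTH) for m in range(0, 14))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset (bit-reproducible given ``seed``)."""

    generating_params: ModelParameters = field(default_factory=ModelParameters)
    ics: InitialConditions = field(default_factory=InitialConditions)
    abeta_times: tuple[float, ...] = field(default_factory=_default_abeta_times)
    abeta_noise_sd: float = 0.5  # pmol/mg
    endpoint_conditions: tuple[tuple[float, float, float, float], ...] = (
        DEFAULT_ENDPOINT_CONDITIONS
    )
    endpoint_noise_sd: float = 0.03  # fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abeta_noise_sd < 0 or self.endpoint_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(t < 0 for t in self.abeta_times):
            raise ValueError("observation times must be >= 0")


def generate_abeta_observations(
    spec: SynthSpec,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> list[AbetaObservation]:
    """Amyloid-load observations: model curve + truncated Gaussian noise."""
    times = np.asarray(spec.abeta_times, dtype=float)
    curve = _simulate_A_at(spec.generating_params, spec.ics, times, rtol, atol)
    rng = np.random.default_rng(spec.seed)
    noisy = curve + rng.normal(0.0, spec.abeta_noise_sd, size=curve.shape)
    noisy = np.clip(noisy, 0.0, None)
    return [AbetaObservation(t=float(t), A_obs=float(a)) for t, a in zip(times, noisy)]


def generate_treatment_endpoints(
    spec: SynthSpec,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> list[TreatmentObservation]:
    """Percent-decrease endpoints per condition, noise truncated to [0, 1]."""
    rng = np.random.default_rng(spec.seed + 1)  # independent of the load stream
    out = []
    for age_months, days, B0, L in spec.endpoint_conditions:
        probe = TreatmentObservation(age_months=age_months, days_treated=days, B0=B0, L=L)
        delta = _simulated_pct_decrease(spec.generating_params, spec.ics, probe, rtol, atol)
        noisy = float(np.clip(delta + rng.normal(0.0, spec.endpoint_noise_sd), 0.0, 1.0))
        out.append(
            TreatmentObservation(
                age_months=age_months,
                days_treated=days,
                B0=B0,
                L=L,
                pct_decrease_obs=noisy,
            )
        )
    return out


def write_fixtures(directory: str | Path, spec: SynthSpec | None = None) -> dict[str, Path]:
    """Write a complete synthetic fitting dataset into ``directory``.

    Emits the same CSV schemas the fitting module reads:
    ``abeta_load.csv`` and ``treatment_endpoints.csv``.
    """
    spec = spec or SynthSpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    abeta_path = directory / "abeta_load.csv"
    endpoints_path = directory / "treatment_endpoints.csv"
    write_abeta_csv(generate_abeta_observations(spec), abeta_path)
    write_treatment_csv(generate_treatment_endpoints(spec), endpoints_path)
    return {"abeta_load": abeta_path, "treatment_endpoints": endpoints_path}
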