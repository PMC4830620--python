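"""Experiment tests: endpoint metrics, dose sweeps, critical-dose search,
dose equivalence and the parameter sensitivity table."""

import numpy as np
import pytest

from bexsim import (
    DosingRegimen,
    InitialConditions,
    ModelParameters,
    critical_dose,
    dose_frequency_sweep,
    equivalent_dose,
    percent_decrease_abeta,
    percent_increase_cells,
    run_life_course,
    sensitivity_table,
    simulate,
)
from bexsim.experiments import treatment_endpoint_states
from bexsim.simulate import Trajectory


def _mini_traj(t_final, N, Nd=1.0, A=1.0, P0=0.0):
    times = np.array([0.0, t_final])
    y = np.array([[N, Nd, A, P0], [N, Nd, A, P0]])
    return Trajectory(times=times, y=y, bex=np.zeros(2))


class TestEndpointMetrics:
    def test_percent_decrease_arithmetic(self):
        u = _mini_traj(10.0, N=50.0, A=10.0)
        t = _mini_traj(10.0, N=50.0, A=7.0)
        assert percent_decrease_abeta(u, t) == pytest.approx(0.30)
        assert percent_decrease_abeta(u, u) == 0.0

    def test_percent_increase_arithmetic(self):
        u = _mini_traj(10.0, N=50.0)
        t = _mini_traj(10.0, N=60.0)
        assert percent_increase_cells(u, t) == pytest.approx(0.20)
        assert percent_increase_cells(u, u) == 0.0

    def test_mismatched_end_times_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease_abeta(_mini_traj(10.0, N=1.0), _mini_traj(11.0, N=1.0))

    def test_zero_reference_rejected(self):
        u = _mini_traj(10.0, N=50.0, A=0.0)
        with pytest.raises(ZeroDivisionError):
            percent_decrease_abeta(u, u)

    def test_grid_invariance(self, params, ics):
        """The metrics depend only on endpoint states, not the output grid."""
        reg = DosingRegimen(B0=100.0, t_B=120.0, L=1.0)
        u_coarse = simulate(params, ics, DosingRegimen.untreated(), 134.0, output_step=2.0)
        u_fine = simulate(params, ics, DosingRegimen.untreated(), 134.0, output_step=0.25)
        t_coarse = simulate(params, ics, reg, 134.0, output_step=2.0)
        t_fine = simulate(params, ics, reg, 134.0, output_step=0.25)
        a = percent_decrease_abeta(u_coarse, t_coarse)
        b = percent_decrease_abeta(u_fine, t_fine)
        assert a == pytest.approx(b, rel=1e-7)

    def test_treated_seven_day_endpoint_pin(self, params, ics):
        """Regression pin: six-month-old, 100 mg/kg daily for 7 days gives a
        ~29% decrease in soluble amyloid (value frozen from this model)."""
        u, t = treatment_endpoint_states(params, ics, 6.0, 7.0, 100.0)
        delta = (u.A - t.A) / u.A
        assert delta == pytest.approx(0.2910, abs=0.002)


@pytest.fixture(scope="module")
def sweep(params):
    doses = [0.0, 10.0, 50.0, 100.0, 300.0, 1000.0]
    return dose_frequency_sweep(params, 6.0, 14.0, doses)


@pytest.fixture(scope="module")
def records(params):
    return sensitivity_table(params)


class TestDoseFrequencySweep:
    def test_zero_dose_is_mode_independent(self, sweep):
        at_zero = sweep.table[sweep.table["dose"] == 0.0]["final_N"]
        assert at_zero.nunique() == 1

    def test_monotone_in_dose_within_mode(self, sweep):
        for mode, grp in sweep.table.groupby("mode"):
            ordered = grp.sort_values("dose")["final_N"].to_numpy()
            assert np.all(np.diff(ordered) >= -1e-9), mode

    def test_constant_most_effective_at_fixed_dose(self, sweep):
        """At a fixed 100 mg/kg, longer exposure beats sparser pulses."""
        n = {m: sweep.final_N(100.0, m) for m in ("constant", "daily", "weekly")}
        assert n["constant"] > n["daily"] > n["weekly"]

    def test_grid_must_include_zero(self, params):
        with pytest.raises(ValueError):
            dose_frequency_sweep(params, 6.0, 14.0, [10.0, 100.0])

    def test_complete_grid(self, sweep):
        assert len(sweep.table) == 6 * 4
        assert not sweep.table["final_N"].isna().any()
        assert (sweep.table["final_N"] >= 0).all()


class TestCriticalDose:
    def test_degenerate_dynamics_returns_zero(self, ics):
        """With (numerically) no disease flux, no dose is needed."""
        p = ModelParameters(lambda_d=1e-12)
        dose = critical_dose(p, 4.0, 14.0, criterion="net_recovery")
        assert dose == 0.0

    def test_net_recovery_threshold_is_a_sign_change(self, params, ics):
        """Final N minus start N crosses zero at the returned dose."""
        dose = critical_dose(params, 5.0, 14.0, criterion="net_recovery", resolution=1.0)
        u_lo, t_lo = treatment_endpoint_states(params, ics, 5.0, 14.0, dose - 2.0)
        u_hi, t_hi = treatment_endpoint_states(params, ics, 5.0, 14.0, dose + 2.0)
        from bexsim import age_months_to_days, untreated_state_at

        n_start = untreated_state_at(params, ics, age_months_to_days(5.0)).N
        assert t_lo.N < n_start < t_hi.N

    def test_nondecreasing_in_age(self, params):
        """Older mice need more drug (under both search criteria)."""
        net = [critical_dose(params, a, 14.0, criterion="net_recovery") for a in (4, 5, 6)]
        assert net[0] <= net[1] <= net[2]
        elbow = [critical_dose(params, a, 14.0, criterion="elbow") for a in (4, 5, 6)]
        assert elbow[0] <= elbow[1] <= elbow[2]

    def test_nonincreasing_in_duration(self, params):
        """Longer treatment never raises the threshold (age 5 months)."""
        doses = [critical_dose(params, 5.0, d, criterion="net_recovery") for d in (7, 14, 28)]
        assert doses[0] >= doses[1] >= doses[2]

    def test_unreachable_criterion_returns_none(self, params):
        """A 9-month-old cannot recover net cells in 3 days at <= 1000 mg/kg."""
        assert critical_dose(params, 9.0, 3.0, criterion="net_recovery") is None


class TestEquivalentDose:
    def test_fixed_point(self, params):
        """Matching a daily regimen in daily mode returns the same dose."""
        ref = DosingRegimen(B0=100.0, L=1.0)
        dose = equivalent_dose(params, 6.0, 14.0, ref, "daily", dose_bounds=(0.0, 1000.0))
        assert dose == pytest.approx(100.0, abs=0.2)

    def test_idempotent_composition(self, params):
        """The equivalent of the equivalent returns the original dose."""
        ref = DosingRegimen(B0=100.0, L=1.0)
        const = equivalent_dose(params, 6.0, 14.0, ref, "constant", dose_bounds=(0.0, 1000.0))
        back = equivalent_dose(
            params, 6.0, 14.0,
            DosingRegimen(B0=const, mode="constant"), "daily",
            dose_bounds=(0.0, 1000.0),
        )
        assert back == pytest.approx(100.0, abs=0.5)

    def test_no_bracket_returns_none(self, params):
        """A weekly dose capped far below the reference effect cannot match."""
        ref = DosingRegimen(B0=1000.0, L=1.0)
        assert (
            equivalent_dose(params, 6.0, 14.0, ref, "weekly", dose_bounds=(0.0, 10.0)) is None
        )


class TestSensitivityTable:
    def test_cardinality(self, records):
        assert len(records) == 12  # 6 parameters x 2 scenario doses

    def test_zero_perturbation_is_null(self, params):
        recs = sensitivity_table(params, perturbation=0.0)
        assert all(r.pct_change_N == 0.0 for r in recs)

    def test_kB_structural_zero_untreated(self, records):
        """k_B multiplies the drug level, so it cannot act at dose 0."""
        rec = next(r for r in records if r.parameter == "k_B" and r.dose == 0.0)
        assert rec.pct_change_N == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_rerun(self, params, ics):
        """A record equals an independent rerun with the parameter hand-edited."""
        records = sensitivity_table(params, doses=(100.0,))
        rec = next(r for r in records if r.parameter == "lambda_d")
        edited = params.replace(lambda_d=params.lambda_d * 1.1)
        base_traj = run_life_course(params, 9.0, DosingRegimen(B0=100.0, L=1.0), 90.0,
                                    output_step=5.0, treatment_output_step=0.5)
        edited_traj = run_life_course(edited, 9.0, DosingRegimen(B0=100.0, L=1.0), 90.0,
                                      output_step=5.0, treatment_output_step=0.5)
        expected = 100.0 * (edited_traj.N[-1] - base_traj.N[-1]) / base_traj.N[-1]
        assert rec.pct_change_N == pytest.approx(expected, rel=1e-4)
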