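import numpy as np
import pytest
from scipy.integrate import solve_ivp

from btksim import (
    PDParameters,
    PKParameters,
    occupancy_percent,
    ode_rhs,
    qd_regimen,
    simulate_individual,
    steady_state_occupancy_constant_C,
)


class TestRHS:
    def test_empty_system_synthesizes_btk_only(self, pk_typical, pd_slow):
        dy = ode_rhs(0.0, np.zeros(6), pk_typical, pd_slow)
        assert dy[3] == pytest.approx(pd_slow.ksyn)
        assert np.allclose(np.delete(dy, 3), 0.0)

    def test_baseline_is_steady_state_without_drug(self, pk_typical, pd_slow):
        y = np.array([0.0, 0.0, 0.0, pd_slow.btk0, 0.0, 0.0])
        dy = ode_rhs(0.0, y, pk_typical, pd_slow)
        assert np.allclose(dy, 0.0, atol=1e-14)

    def test_covalent_pool_driven_by_reversible_complex(self, pk_typical, pd_slow):
        # no drug in plasma: covalent pool gains kinact*rc and loses kdeg*cc
        y = np.array([0.0, 0.0, 0.0, 0.5, 0.2, 0.3])
        dy = ode_rhs(0.0, y, pk_typical, pd_slow)
        assert dy[5] == pytest.approx(pd_slow.kinact * 0.2 - pd_slow.kdeg * 0.3)

    def test_binding_does_not_deplete_drug(self, pk_typical, pd_slow):
        # central-amount balance has no term in the BTK states
        y1 = np.array([0.0, 1000.0, 0.0, 1.04, 0.0, 0.0])
        y2 = np.array([0.0, 1000.0, 0.0, 0.1, 0.5, 0.4])
        d1 = ode_rhs(0.0, y1, pk_typical, pd_slow)
        d2 = ode_rhs(0.0, y2, pk_typical, pd_slow)
        assert d1[:3] == pytest.approx(d2[:3])


class TestOccupancy:
    @pytest.mark.parametrize(
        "f, rc, cc, expected",
        [(1.04, 0.0, 0.0, 0.0), (0.05, 0.001, 0.99, 95.20), (0.0, 0.0, 1.0, 100.0)],
    )
    def test_bound_fraction(self, f, rc, cc, expected):
        assert occupancy_percent(f, rc, cc) == pytest.approx(expected, abs=5e-3)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            occupancy_percent(0.0, 0.0, 0.0)


class TestSteadyStateOracle:
    def test_no_drug(self, pd_slow):
        assert steady_state_occupancy_constant_C(0.0, pd_slow) == 0.0

    def test_saturation_limit(self, pd_slow):
        assert steady_state_occupancy_constant_C(1e9, pd_slow) > 99.999

    @pytest.mark.parametrize("c", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_matches_long_horizon_numeric_plateau(self, pd_slow, c):
        """Closed-form plateau vs direct integration of the binding ODEs at
        constant free concentration, run to 20 BTK half-lives."""

        def rhs(t, y):
            f, rc, cc = y
            bind = pd_slow.kon * f * c
            return [
                pd_slow.ksyn - bind + pd_slow.koff * rc - pd_slow.kdeg * f,
                bind - (pd_slow.koff + pd_slow.kinact) * rc,
                pd_slow.kinact * rc - pd_slow.kdeg * cc,
            ]

        t_end = 20.0 * pd_slow.t_half_btk
        sol = solve_ivp(rhs, (0.0, t_end), [pd_slow.btk0, 0.0, 0.0],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        numeric = occupancy_percent(*sol.y[:, -1])
        analytic = steady_state_occupancy_constant_C(c, pd_slow)
        assert numeric == pytest.approx(analytic, abs=0.1)


class TestIndividualSimulation:
    def test_no_drug_identity(self, pk_typical, pd_slow):
        t = np.arange(0.0, 169.0, 1.0)
        traj = simulate_individual(pk_typical, pd_slow, [], t)
        assert np.allclose(traj.btk_f, pd_slow.btk0, atol=1e-8)
        assert np.allclose(traj.occupancy, 0.0, atol=1e-6)
        assert np.allclose(traj.c2_free, 0.0)

    def test_return_to_baseline_closed_form(self, pk_typical, pd_slow):
        """A perturbed free-BTK level relaxes as btk0 + (x0-btk0)e^{-kdeg t}."""
        x0 = 0.3

        def rhs(t, y):
            return ode_rhs(t, y, pk_typical, pd_slow)

        t = np.linspace(0.0, 240.0, 49)
        sol = solve_ivp(rhs, (0.0, 240.0), [0, 0, 0, x0, 0, 0], t_eval=t,
                        method="LSODA", rtol=1e-10, atol=1e-13)
        expected = pd_slow.btk0 + (x0 - pd_slow.btk0) * np.exp(-pd_slow.kdeg * t)
        assert np.max(np.abs(sol.y[3] - expected)) < 1e-6

    def test_pk_linearity_in_dose(self, pk_typical, pd_slow):
        t = np.arange(0.0, 169.0, 4.0)
        lo = simulate_individual(pk_typical, pd_slow, qd_regimen(140, 7), t)
        hi = simulate_individual(pk_typical, pd_slow, qd_regimen(280, 7), t)
        nz = lo.c2_free > 0
        assert np.max(np.abs(hi.c2_free[nz] / lo.c2_free[nz] - 2.0)) < 1e-6

    def test_occupancy_invariant_to_btk_baseline(self, pk_typical):
        """Binding does not feed back on drug, and the BTK block is linear in
        the BTK states, so occupancy is independent of BTK0."""
        t = np.arange(0.0, 169.0, 4.0)
        a = simulate_individual(pk_typical, PDParameters(btk0=1.04), qd_regimen(420, 7), t,
                                rtol=1e-11, atol=1e-14)
        b = simulate_individual(pk_typical, PDParameters(btk0=2.08), qd_regimen(420, 7), t,
                                rtol=1e-11, atol=1e-14)
        assert np.max(np.abs(a.occupancy - b.occupancy)) < 1e-8

    def test_occupancy_bounded_and_states_nonnegative(self, pk_typical, pd_fast):
        t = np.arange(0.0, 169.0, 1.0)
        traj = simulate_individual(pk_typical, pd_fast, qd_regimen(560, 7), t)
        assert np.all(traj.occupancy >= 0.0) and np.all(traj.occupancy <= 100.0)
        for arr in (traj.a1, traj.a2, traj.a3, traj.btk_f, traj.btk_rc, traj.btk_cc):
            assert np.all(arr >= 0.0)

    def test_total_btk_approximately_conserved_at_steady_state(self, pk_typical, pd_slow):
        """kdegc = kdeg and a transiently small reversible complex keep total
        BTK within ~2% of baseline over days 4-7 of 420 mg QD."""
        t = np.arange(96.0, 169.0, 2.0)
        traj = simulate_individual(pk_typical, pd_slow, qd_regimen(420, 7),
                                   np.concatenate([[0.0], t]))
        total = traj.btk_f + traj.btk_rc + traj.btk_cc
        rel = np.abs(total[1:] - pd_slow.btk0) / pd_slow.btk0
        assert np.max(rel) < 0.02

    def test_typical_free_btk_knockdown_at_trough(self, pk_typical, pd_slow):
        traj = simulate_individual(pk_typical, pd_slow, qd_regimen(420, 7),
                                   np.array([0.0, 168.0]))
        assert traj.btk_f[-1] <= 0.05 * pd_slow.btk0

    def test_dose_event_outside_span_rejected(self, pk_typical, pd_slow):
        with pytest.raises(ValueError):
            simulate_individual(pk_typical, pd_slow, qd_regimen(420, 7),
                                np.array([0.0, 24.0]))

    def test_trajectory_export_columns(self, pk_typical, pd_slow):
        traj = simulate_individual(pk_typical, pd_slow, qd_regimen(140, 1),
                                   np.arange(0.0, 25.0, 1.0))
        df = traj.to_frame()
        assert list(df.columns) == [
            "time_h", "a1_ug", "a2_ug", "a3_ug", "btkf_nM", "btkrc_nM",
            "btkcc_nM", "c2free_nM", "occupancy_pct",
        ]
        assert len(df) == 25


from hypothesis import given, settings, strategies as st

positive = st.floats(1e-9, 1e3)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(f=positive, rc=positive, cc=positive)
def test_occupancy_always_within_percent_bounds(f, rc, cc):
    occ = occupancy_percent(f, rc, cc)
    assert 0.0 <= occ <= 100.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(c=st.floats(0.0, 1e4))
def test_steady_state_occupancy_monotone_in_concentration(c):
    pd_ = PDParameters()
    assert steady_state_occupancy_constant_C(c, pd_) <= \
        steady_state_occupancy_constant_C(c * 2.0 + 1e-6, pd_)
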