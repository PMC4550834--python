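"""Unit and property tests for the cell-cycle population model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from ddrcycle import (
    CellCycleParams,
    CellCycleState,
    ExposureSchedule,
    apply_ir,
    cell_cycle_rhs,
    cycle_seed_state,
    gammah2ax_percent,
    phase_fractions,
    repair_rate,
    simulate_invitro,
    total_cells,
)
from ddrcycle.cell_cycle import COMPARTMENTS, cycle_matrix, system_matrix


def reference_matrix(p: CellCycleParams, conc: float) -> np.ndarray:
    """Rate matrix built independently, entry by entry, from the model description."""
    kr = p.k3 * p.ki / (p.ki + conc)
    kio = p.k_ir_repair + p.k_ir_death
    A = np.zeros((7, 7))
    A[0, 0] = -p.k1; A[0, 3] = 2 * p.km; A[0, 4] = p.k_ir_repair
    A[1, 0] = p.k1 * (1 - p.k2); A[1, 1] = -p.ks; A[1, 2] = kr; A[1, 5] = p.k_ir_repair
    A[2, 0] = p.k1 * p.k2; A[2, 2] = -(kr + p.k4)
    A[3, 1] = p.ks; A[3, 3] = -p.km; A[3, 6] = p.k_ir_repair
    A[4, 4] = A[5, 5] = A[6, 6] = -kio
    return A


class TestRepairRate:
    @pytest.mark.parametrize(
        "k3,ki,conc,expected",
        [
            (0.1, 1.0, 0.0, 0.1),         # no-drug limit returns k3
            (0.1, 1.0, 1.0, 0.05),        # half-inhibition at conc = ki
            (0.1, 1.0, 30.0, 0.1 / 31),   # closed form at saturating drug
        ],
    )
    def test_closed_form(self, k3, ki, conc, expected):
        p = CellCycleParams(k3=k3, ki=ki)
        assert repair_rate(p, conc) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_conc(self, params):
        concs = np.linspace(0, 30, 50)
        rates = [repair_rate(params, c) for c in concs]
        assert np.all(np.diff(rates) < 0)

    def test_negative_conc_rejected(self, params):
        with pytest.raises(ValueError):
            repair_rate(params, -0.1)


class TestRhs:
    def test_zero_state_gives_zero_derivative(self, params):
        d = cell_cycle_rhs(CellCycleState(), params, 5.0)
        assert np.all(d == 0)

    def test_hand_evaluated_g1_only(self):
        p = CellCycleParams(k1=0.05, k2=0.2)
        d = cell_cycle_rhs(CellCycleState(g1=1.0), p, 0.0)
        assert d[0] == pytest.approx(-0.05)
        assert d[1] == pytest.approx(0.04)
        assert d[2] == pytest.approx(0.01)
        assert np.all(d[3:] == 0)

    def test_no_damage_inflow_when_k2_zero(self, params):
        p = params.with_updates(k2=0.0)
        state = CellCycleState(g1=10, s=5, g2m=3)
        assert cell_cycle_rhs(state, p, 0.0)[2] == 0.0

    def test_matches_independent_matrix(self, params, rng):
        x = rng.uniform(0, 50, size=7)
        state = CellCycleState.from_array(x)
        for conc in (0.0, 0.3, 3.0, 30.0):
            expected = reference_matrix(params, conc) @ x
            np.testing.assert_allclose(cell_cycle_rhs(state, params, conc), expected,
                                       rtol=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=20)
    def test_linear_in_state(self, scale):
        p = CellCycleParams()
        x = np.array([5.0, 3.0, 1.0, 2.0, 0.5, 0.2, 0.1])
        d1 = system_matrix(p, 1.0) @ x
        d2 = system_matrix(p, 1.0) @ (scale * x)
        np.testing.assert_allclose(d2, scale * d1, rtol=1e-12)


class TestApplyIr:
    def test_zero_dose_is_identity(self, seed_state, params):
        assert apply_ir(seed_state, 0.0, params) == seed_state

    def test_saturating_dose_moves_everything(self, seed_state, params):
        hit = apply_ir(seed_state, 1e6, params)
        assert hit.g1 == pytest.approx(0.0, abs=1e-9)
        assert hit.s == pytest.approx(0.0, abs=1e-9)
        assert hit.g2m == pytest.approx(0.0, abs=1e-9)
        assert hit.total == pytest.approx(seed_state.total)

    def test_single_hit_fraction(self):
        p = CellCycleParams(alpha_ir=0.5)
        hit = apply_ir(CellCycleState(g1=100.0), 2.0, p)
        assert hit.g1 == pytest.approx(100 * np.exp(-1.0), rel=1e-12)
        assert hit.g1ir == pytest.approx(100 * (1 - np.exp(-1.0)), rel=1e-12)

    def test_damaged_s_moves_to_ir_ledger(self, params):
        hit = apply_ir(CellCycleState(sd=10.0), 2.0, params)
        f = 1 - np.exp(-params.alpha_ir * 2.0)
        assert hit.sir == pytest.approx(10 * f, rel=1e-12)

    @given(dose=st.floats(0.0, 50.0),
           cells=st.lists(st.floats(0.0, 1e6), min_size=7, max_size=7))
    @settings(deadline=None, max_examples=50)
    def test_conserves_total_cells(self, dose, cells):
        p = CellCycleParams()
        state = CellCycleState.from_array(np.array(cells))
        hit = apply_ir(state, dose, p)
        assert hit.total == pytest.approx(state.total, rel=1e-12, abs=1e-9)

    def test_negative_dose_rejected(self, seed_state, params):
        with pytest.raises(ValueError):
            apply_ir(seed_state, -1.0, params)


class TestReadouts:
    def test_no_damage_means_zero_percent(self, params):
        state = CellCycleState(g1=50, s=30, g2m=20)
        assert gammah2ax_percent(state, params) == 0.0

    def test_scaled_damaged_fraction(self):
        p = CellCycleParams(z=0.8)
        state = CellCycleState(g1=40, s=20, sd=25, g2m=15)
        assert gammah2ax_percent(state, p) == pytest.approx(20.0)

    def test_saturation_at_unit_scale(self):
        p = CellCycleParams(z=1.0, z_ir=1.0)
        assert gammah2ax_percent(CellCycleState(sd=42.0), p) == pytest.approx(100.0)

    def test_empty_population_rejected(self, params):
        with pytest.raises(ValueError):
            gammah2ax_percent(CellCycleState(), params)

    def test_total_cells_sums_compartments(self):
        state = CellCycleState(g1=1, s=2, sd=3, g2m=4)
        assert total_cells(state) == pytest.approx(10.0)

    def test_phase_fractions_map_damage_to_phases(self):
        state = CellCycleState(g1=50, sd=30, g2m=20)
        assert phase_fractions(state) == pytest.approx((50.0, 30.0, 20.0))

    def test_phase_fractions_include_ir_twins_and_sum_to_100(self, rng):
        state = CellCycleState.from_array(rng.uniform(1, 10, 7))
        fr = phase_fractions(state)
        assert sum(fr) == pytest.approx(100.0)
        g1_share = (state.g1 + state.g1ir) / state.total * 100
        assert fr[0] == pytest.approx(g1_share)


class TestSimulateInvitro:
    def test_zero_population_stays_zero(self, params):
        # simulate from an all-but-empty population (exact zero is rejected by readouts)
        traj = simulate_invitro(CellCycleState(), params,
                                ExposureSchedule.constant(1.0), np.linspace(0, 48, 5))
        assert np.all(traj.states == 0)

    @pytest.mark.parametrize("conc", [0.0, 3.0, 30.0])
    def test_matches_matrix_exponential_oracle(self, seed_state, params, conc):
        """Constant exposure: trajectory equals expm(A t) x0 to 1e-6 relative."""
        times = np.linspace(0, 48, 10)
        traj = simulate_invitro(seed_state, params, ExposureSchedule.constant(conc), times)
        A = reference_matrix(params, conc)
        x0 = seed_state.as_array()
        for i, t in enumerate(times):
            oracle = expm(A * t) @ x0
            np.testing.assert_allclose(traj.states[i], oracle, rtol=1e-6, atol=1e-10)

    def test_expm_solver_agrees_with_lsoda(self, seed_state, params):
        times = np.linspace(0, 72, 7)
        sched = ExposureSchedule.washout(3.0, 16.0)
        t1 = simulate_invitro(seed_state, params, sched, times)
        t2 = simulate_invitro(seed_state, params, sched, times, solver="expm")
        np.testing.assert_allclose(t1.states, t2.states, rtol=1e-6, atol=1e-8)

    def test_growth_rate_matches_dominant_eigenvalue(self, params):
        """Damage-free growth converges to the cycle matrix's leading eigenvalue."""
        p = params.with_updates(k2=0.0)
        lam = np.max(np.linalg.eigvals(cycle_matrix(p)).real)
        traj = simulate_invitro(cycle_seed_state(100.0, p), p,
                                ExposureSchedule.constant(0.0),
                                np.array([0.0, 400.0, 500.0]))
        n = traj.total_cells
        growth = np.log(n[2] / n[1]) / 100.0
        assert growth == pytest.approx(lam, rel=1e-3)

    def test_dose_monotonicity_at_48h(self, seed_state, params):
        """γH2AX % rises and cell count falls with dose (low at 0.3 μM, saturating >3 μM)."""
        doses = [0.0, 0.3, 1.0, 3.0, 10.0, 30.0]
        g, n = [], []
        for d in doses:
            traj = simulate_invitro(seed_state, params, ExposureSchedule.constant(d),
                                    np.array([0.0, 48.0]), solver="expm")
            g.append(traj.gammah2ax_pct[-1])
            n.append(traj.total_cells[-1])
        assert np.all(np.diff(g) >= 0)
        assert np.all(np.diff(n) <= 0)

    def test_washout_returns_toward_control(self, seed_state, params):
        """After wash-out at 16 h the γH2AX signal decays back to the drug-free level."""
        times = np.arange(0.0, 73.0, 4.0)
        washed = simulate_invitro(seed_state, params,
                                  ExposureSchedule.washout(3.0, 16.0), times)
        control = simulate_invitro(seed_state, params,
                                   ExposureSchedule.constant(0.0), times)
        g = washed.gammah2ax_pct
        peak = g[times == 16.0][0]
        assert g[-1] < peak
        assert abs(g[-1] - control.gammah2ax_pct[-1]) < 5.0

    def test_non_negative_trajectories(self, seed_state, params):
        sched = ExposureSchedule(segments=((0.0, 10.0), (16.0, 0.0)),
                                 ir_events=((24.0, 2.0),))
        traj = simulate_invitro(seed_state, params, sched, np.arange(0.0, 72.1, 2.0))
        assert np.all(traj.states >= 0)

    def test_ir_event_populates_twins_and_conserves(self, seed_state, params):
        sched = ExposureSchedule(ir_events=((0.0, 2.0),))
        traj = simulate_invitro(seed_state, params, sched, np.array([0.0, 1.0]))
        assert traj.states[0, 4:].sum() > 0
        assert traj.total_cells[0] == pytest.approx(seed_state.total, rel=1e-12)

    def test_non_increasing_times_rejected(self, seed_state, params):
        with pytest.raises(ValueError):
            simulate_invitro(seed_state, params, ExposureSchedule.constant(0.0),
                             np.array([0.0, 10.0, 5.0]))


class TestSchedule:
    def test_conc_at_follows_segments(self):
        sched = ExposureSchedule(segments=((0.0, 3.0), (16.0, 0.0)))
        assert sched.conc_at(0.0) == 3.0
        assert sched.conc_at(15.9) == 3.0
        assert sched.conc_at(16.0) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"segments": ((5.0, 1.0), (5.0, 2.0))},
            {"segments": ((0.0, -1.0),)},
            {"ir_events": ((1.0, -2.0),)},
            {"segments": ()},
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExposureSchedule(**kwargs)


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"k1": -0.1}, {"k2": 1.5}, {"ki": 0.0}, {"z": 0.0}, {"k4": np.nan},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CellCycleParams(**kwargs)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            CellCycleState(g1=-1.0)
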