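"""Tests for the shell/core xenograft model."""

import numpy as np
import pytest

from ddrcycle import (
    CellCycleState,
    PKParams,
    Regimen,
    RegimenSpec,
    TumorParams,
    TumorState,
    build_regimen,
    initial_tumor_state,
    simulate_xenograft,
    tumor_rhs,
    tumor_volume,
)
from ddrcycle.cell_cycle import _apply_ir_array
from ddrcycle.tumor import _tumor_rhs_array


@pytest.fixture
def small_tumor(tumor_params):
    # small cell numbers keep hand analysis simple; dynamics are scale-free
    return TumorParams(cycle=tumor_params.cycle, kx=tumor_params.kx,
                       shell_coeff=0.5, v_cell=1e-9, v0=1e-3)


class TestTumorRhs:
    def test_empty_tumor_zero_derivative(self, tumor_params):
        state = TumorState(shell=CellCycleState(), core=CellCycleState())
        assert np.all(tumor_rhs(state, tumor_params, 0.0) == 0.0)

    def test_no_transfer_at_exact_capacity(self, tumor_params):
        """At Ns = a·Ntot^(2/3) the relaxation flux vanishes."""
        state0 = initial_tumor_state(tumor_params)
        d_with = _tumor_rhs_array(state0.as_array(), tumor_params, 0.0)
        # same cell-cycle dynamics with transfer disabled (kx -> tiny)
        slow = TumorParams(cycle=tumor_params.cycle, kx=1e-12,
                           shell_coeff=tumor_params.shell_coeff,
                           v_cell=tumor_params.v_cell, v0=tumor_params.v0)
        d_without = _tumor_rhs_array(state0.as_array(), slow, 0.0)
        # atol covers float round-off of the capacity term on ~1e8 cells
        np.testing.assert_allclose(d_with, d_without, rtol=1e-9, atol=1e-4)

    def test_core_has_no_g1_commitment(self, tumor_params):
        state = TumorState(shell=CellCycleState(), core=CellCycleState(g1=1000.0))
        d = tumor_rhs(state, tumor_params, 0.0)
        # core G1 cells rest: only transfer (core->shell, shell empty) moves them
        core_d = d[7:]
        assert core_d[1] == 0.0 and core_d[2] == 0.0  # no S inflow of either kind

    def test_transfer_preserves_phase_composition(self, tumor_params):
        shell = CellCycleState(g1=10.0)          # far below capacity -> core refills shell
        core = CellCycleState(g1=600.0, s=300.0, g2m=100.0)
        d = tumor_rhs(TumorState(shell=shell, core=core), tumor_params, 0.0)
        # total-cell balance: transfer cancels; only division and death remain
        p = tumor_params.cycle
        expected_net = p.km * (0.0 + core.g2m)   # no damage, no IR: death terms zero
        assert d.sum() == pytest.approx(expected_net, rel=1e-9)
        # core loses proportionally to its composition (0.6, 0.3, 0.1)
        flux_part = d[7] - 0.0  # g1 core deriv includes -flux*0.6 + cycle terms
        assert flux_part < 0

    def test_bookkeeping_along_trajectory(self, tumor_params, pk_params):
        """d(total)/dt equals division inflow minus death outflow at sampled states."""
        reg = build_regimen(RegimenSpec(drug_dose_mg_kg=25.0, frequency="QD",
                                        drug_days=(0, 1, 2, 3),
                                        ir_dose_gy=2.0, ir_days=(0, 1)))
        times = np.linspace(0.0, 120.0, 25)
        traj = simulate_xenograft(tumor_params, pk_params, reg, times)
        p = tumor_params.cycle
        for i in range(0, len(times), 6):
            y = traj.states[i]
            d = _tumor_rhs_array(y, tumor_params, traj.conc[i])
            division = p.km * (y[3] + y[10])
            death = p.k4 * (y[2] + y[9]) + p.k_ir_death * (y[4:7].sum() + y[11:14].sum())
            assert d.sum() == pytest.approx(division - death, rel=1e-9, abs=1e-6)


class TestTumorVolume:
    def test_empty_tumor_zero_volume(self, tumor_params):
        state = TumorState(shell=CellCycleState(), core=CellCycleState())
        assert tumor_volume(state, tumor_params) == 0.0

    def test_volume_arithmetic(self):
        params = TumorParams(v_cell=1e-9, v0=1.0)
        state = TumorState(shell=CellCycleState(g1=6e8), core=CellCycleState(g1=4e8))
        assert tumor_volume(state, params) == pytest.approx(1.0)

    def test_volume_conserved_across_ir(self, tumor_params):
        state0 = initial_tumor_state(tumor_params)
        y = state0.as_array()
        hit = np.concatenate([
            _apply_ir_array(y[:7], 2.0, tumor_params.cycle),
            _apply_ir_array(y[7:], 2.0, tumor_params.cycle),
        ])
        assert hit.sum() == pytest.approx(y.sum(), rel=1e-12)

    def test_initial_state_matches_v0(self, tumor_params):
        state0 = initial_tumor_state(tumor_params)
        assert tumor_volume(state0, tumor_params) == pytest.approx(tumor_params.v0,
                                                                   rel=1e-9)


class TestSimulateXenograft:
    def test_untreated_growth_monotone_and_decelerating(self, tumor_params, pk_params):
        times = np.arange(0.0, 28 * 24.0 + 1, 24.0)
        traj = simulate_xenograft(tumor_params, pk_params, Regimen(), times)
        vol = traj.volume_cm3
        assert np.all(np.diff(vol) > 0)
        specific = np.diff(np.log(vol)) / 24.0
        assert specific[-1] < specific[0]  # per-cell growth slows as shell fraction shrinks

    def test_shell_tracks_capacity_at_stiff_kx(self, tumor_params, pk_params):
        stiff = TumorParams(cycle=tumor_params.cycle, kx=50.0,
                            shell_coeff=tumor_params.shell_coeff,
                            v_cell=tumor_params.v_cell, v0=tumor_params.v0)
        times = np.arange(0.0, 14 * 24.0 + 1, 24.0)
        traj = simulate_xenograft(stiff, pk_params, Regimen(), times)
        ns = traj.shell_cells
        target = stiff.shell_coeff * traj.total_cells ** (2.0 / 3.0)
        assert np.max(np.abs(ns - target) / target) < 0.01

    def test_ir_fraction_pulses_gammah2ax(self, tumor_params, pk_params):
        reg = Regimen(ir_fractions=((24.0, 2.0),))
        times = np.array([0.0, 23.9, 24.0, 36.0, 72.0])
        traj = simulate_xenograft(tumor_params, pk_params, reg, times)
        g = traj.gammah2ax_pct
        assert g[2] > g[1] + 10.0       # pulse on the fraction
        assert g[4] < g[2]              # decay afterwards

    def test_zero_seed_rejected(self, tumor_params, pk_params):
        empty = TumorState(shell=CellCycleState(), core=CellCycleState())
        with pytest.raises(ValueError):
            simulate_xenograft(tumor_params, pk_params, Regimen(),
                               np.array([0.0, 24.0]), state0=empty)

    def test_dose_ordering_of_final_volume(self, tumor_params, pk_params):
        """Day-28 volume is non-increasing across 0/25/50/80 mg/kg daily dosing."""
        times = np.arange(0.0, 28 * 24.0 + 1, 24.0)
        finals = []
        for dose in (0.0, 25.0, 50.0, 80.0):
            if dose == 0:
                reg = Regimen()
            else:
                reg = build_regimen(RegimenSpec(drug_dose_mg_kg=dose, frequency="QD",
                                                drug_days=tuple(range(21))))
            traj = simulate_xenograft(tumor_params, pk_params, reg, times)
            finals.append(traj.volume_cm3[-1])
        assert np.all(np.diff(finals) <= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TumorParams(v0=0.0)
        with pytest.raises(ValueError):
            TumorParams(kx=-1.0)
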