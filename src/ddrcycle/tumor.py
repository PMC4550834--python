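"""Multi-scale xenograft model: proliferating shell, inert core, PK coupling.

The tumor is represented as two copies of the cell-cycle model: an outer
proliferating shell exposed to the full dynamics and an inner core in
which G1 → S commitment is switched off (cells already in S or G2/M
complete the cycle, then rest in G1).  The shell holds a capacity
``Ns* = a·Ntot^(2/3)`` — the cell number of a fixed-thickness rim on a
sphere — and a relaxation flux ``J = kx·(Ns − Ns*)`` moves cells
shell → core when the shell is over capacity and core → shell when death
depletes the shell, each cell keeping its cycle phase.  Tumor volume is
total cell number times a fixed per-cell volume.

Drug arrives through the two-compartment PK model; IR fractions hit shell
and core alike.  Both couplings use the same event-breakpoint semantics as
the in vitro simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cell_cycle import (
    CellCycleParams,
    CellCycleState,
    IntegrationError,
    _apply_ir_array,
    _gammah2ax_percent_arr,
    cycle_seed_state,
    repair_rate,
)
from .pk import PKParams, Regimen, pk_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TumorParams:
    """Geometry and transfer constants wrapped around the cycle parameters."""

    cycle: CellCycleParams = field(default_factory=CellCycleParams)
    kx: float = 1.0                 # shell<->core relaxation rate, 1/h
    shell_coeff: float = 190.0      # a in Ns* = a*Ntot^(2/3), cells^(1/3)
    v_cell: float = 1e-9            # cm3 per cell
    v0: float = 0.25                # initial tumor volume, cm3

    def __post_init__(self) -> None:
        for name in ("kx", "shell_coeff", "v_cell", "v0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"tumor parameter {name} must be > 0")

    def shell_capacity(self, n_total: float) -> float:
        return self.shell_coeff * n_total ** (2.0 / 3.0)


@dataclass(frozen=True)
class TumorState:
    shell: CellCycleState
    core: CellCycleState

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.shell.as_array(), self.core.as_array()])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "TumorState":
        y = np.asarray(y, dtype=float)
        if y.shape != (14,):
            raise ValueError(f"expected 14 compartments, got shape {y.shape}")
        return cls(
            shell=CellCycleState.from_array(y[:7]),
            core=CellCycleState.from_array(y[7:]),
        )

    @property
    def total(self) -> float:
        return self.shell.total + self.core.total


def initial_tumor_state(params: TumorParams) -> TumorState:
    """Seed a tumor of volume ``v0``: shell at capacity, core resting in G1."""
    n_total = params.v0 / params.v_cell
    ns = min(params.shell_capacity(n_total), n_total)
    shell = cycle_seed_state(ns, params.cycle)
    core = CellCycleState(g1=n_total - ns)
    return TumorState(shell=shell, core=core)


def tumor_volume(state: TumorState, params: TumorParams) -> float:
    """Tumor volume in cm³ (all cells, shell plus core)."""
    return state.total * params.v_cell


def _cycle_rhs_inplace(x: np.ndarray, p: CellCycleParams, kr: float, k1: float,
                       out: np.ndarray) -> None:
    """RHS of one cycle-model copy written into ``out`` (k1 overridable for the core)."""
    k_ir_out = p.k_ir_repair + p.k_ir_death
    out[0] = 2.0 * p.km * x[3] + p.k_ir_repair * x[4] - k1 * x[0]
    out[1] = k1 * (1.0 - p.k2) * x[0] + kr * x[2] + p.k_ir_repair * x[5] - p.ks * x[1]
    out[2] = k1 * p.k2 * x[0] - (kr + p.k4) * x[2]
    out[3] = p.ks * x[1] + p.k_ir_repair * x[6] - p.km * x[3]
    out[4] = -k_ir_out * x[4]
    out[5] = -k_ir_out * x[5]
    out[6] = -k_ir_out * x[6]


def _tumor_rhs_array(y: np.ndarray, params: TumorParams, conc: float) -> np.ndarray:
    p = params.cycle
    kr = repair_rate(p, conc)
    dy = np.empty(14)
    shell, core = y[:7], y[7:]
    _cycle_rhs_inplace(shell, p, kr, p.k1, dy[:7])
    _cycle_rhs_inplace(core, p, kr, 0.0, dy[7:])

    ns = shell.sum()
    nc = core.sum()
    flux = params.kx * (ns - params.shell_capacity(max(ns + nc, 0.0)))
    if flux > 0 and ns > 0:        # shell over capacity: push into the core
        per = flux / ns * shell
        dy[:7] -= per
        dy[7:] += per
    elif flux < 0 and nc > 0:      # shell depleted: refill from the core
        per = (-flux) / nc * core
        dy[7:] -= per
        dy[:7] += per
    return dy


def tumor_rhs(state: TumorState, params: TumorParams, conc: float) -> np.ndarray:
    """Time derivative of the 14-compartment tumor state (shell then core)."""
    if conc < 0:
        raise ValueError("drug concentration must be >= 0 μM")
    return _tumor_rhs_array(state.as_array(), params, conc)


@dataclass(frozen=True)
class XenograftTrajectory:
    """Simulated tumor time course with PK and derived readouts."""

    times: np.ndarray        # (n,), hours
    states: np.ndarray       # (n, 14): shell 7 then core 7
    conc: np.ndarray         # (n,), plasma μM
    params: TumorParams

    @property
    def shell_cells(self) -> np.ndarray:
        return self.states[:, :7].sum(axis=1)

    @property
    def core_cells(self) -> np.ndarray:
        return self.states[:, 7:].sum(axis=1)

    @property
    def total_cells(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def volume_cm3(self) -> np.ndarray:
        return self.total_cells * self.params.v_cell

    @property
    def gammah2ax_pct(self) -> np.ndarray:
        """γH2AX % pooled over shell + core (as quantified on whole viable tumor)."""
        pooled = self.states[:, :7] + self.states[:, 7:]
        return _gammah2ax_percent_arr(pooled, self.params.cycle)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.times,
            "volume_cm3": self.volume_cm3,
            "gammaH2AX_pct": self.gammah2ax_pct,
            "shell_cells": self.shell_cells,
            "core_cells": self.core_cells,
            "conc_uM": self.conc,
        })


def simulate_xenograft(
    params: TumorParams,
    pk: PKParams,
    regimen: Regimen,
    times: Sequence[float],
    *,
    state0: TumorState | None = None,
    rtol: float = 1e-8,
    atol_cells: float = 1e-3,
    atol_pk: float = 1e-12,
) -> XenograftTrajectory:
    """Simulate tumor growth under a dosing/IR regimen.

    PK and tumor states are integrated jointly; oral doses and IR fractions
    are integration breakpoints (instantaneous gut deposit, instantaneous
    IR transfer applied to shell and core).  Output at an event time is the
    post-event state.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("output times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("output times must be >= 0 h")
    if state0 is None:
        state0 = initial_tumor_state(params)
    if state0.total <= 0:
        raise ValueError("tumor seed must contain cells (zero-volume seed rejected)")

    A_pk = pk_matrix(pk)
    conv = pk.mw_conv / pk.v1

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty(17)
        dy[:3] = A_pk @ y[:3]
        conc = max(y[1] * conv, 0.0)
        dy[3:] = _tumor_rhs_array(y[3:], params, conc)
        return dy

    dose_at: dict = {}
    for td, amt in regimen.drug_doses:
        dose_at[td + pk.lag_h] = dose_at.get(td + pk.lag_h, 0.0) + amt
    ir_at = dict(regimen.ir_fractions)
    t_end = t[-1]
    breaks = sorted({e for e in dose_at if e <= t_end} | {e for e in ir_at if e <= t_end})

    y = np.concatenate([np.zeros(3), state0.as_array()])
    atol = np.concatenate([np.full(3, atol_pk), np.full(14, atol_cells)])

    def apply_events(tt: float) -> None:
        nonlocal y
        if tt in dose_at:
            y[0] += dose_at.pop(tt)
            logger.debug("oral dose at t=%g h (breakpoint)", tt)
        if tt in ir_at:
            dose = ir_at.pop(tt)
            y[3:10] = _apply_ir_array(y[3:10], dose, params.cycle)
            y[10:17] = _apply_ir_array(y[10:17], dose, params.cycle)
            logger.debug("IR fraction at t=%g h (breakpoint)", tt)

    out = np.empty((len(t), 17))
    emitted = 0
    cursor = 0.0
    apply_events(0.0)
    while emitted < len(t) and t[emitted] == cursor:
        out[emitted] = y
        emitted += 1

    for b in [bb for bb in breaks if bb > 0.0] + [t_end]:
        if b <= cursor:
            continue
        t_req = t[(t > cursor) & (t < b)]
        sol = solve_ivp(
            rhs, (cursor, b), y,
            t_eval=np.concatenate([t_req, [b]]),
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"xenograft integration failed on segment [{cursor}, {b}] h: {sol.message}"
            )
        out[emitted:emitted + len(t_req)] = sol.y.T[:-1]
        emitted += len(t_req)
        y = sol.y[:, -1]
        cursor = b
        apply_events(cursor)
        while emitted < len(t) and t[emitted] == cursor:
            out[emitted] = y
            emitted += 1

    states = np.clip(out[:, 3:], 0.0, None)
    conc = np.clip(out[:, 1], 0.0, None) * conv
    return XenograftTrajectory(times=t, states=states, conc=conc, params=params)
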