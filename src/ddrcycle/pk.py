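"""Two-compartment pharmacokinetics with first-order oral absorption.

Amount-based formulation over (gut, central, peripheral) in mg/kg:

    dGut/dt = −ka·Gut
    dC1/dt  =  ka·F·Gut − (CL/V1)·C1 − (Q/V1)·C1 + (Q/V2)·C2
    dC2/dt  =  (Q/V1)·C1 − (Q/V2)·C2

Plasma concentration is ``C1/V1`` (mg/L) times ``mw_conv`` (μM per mg/L,
i.e. 1000/molecular weight).  Doses are instantaneous gut deposits, so
the system is linear and superposition across doses holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cell_cycle import _propagate_constant

#: μM per mg/L for a 412.5 g/mol small molecule (the ATR inhibitor studied here).
DEFAULT_MW_CONV = 1000.0 / 412.5


@dataclass(frozen=True)
class PKParams:
    """Two-compartment oral PK constants (per-kg normalized).

    The defaults are a plausible small-molecule mouse parameter set kept as
    an uncalibrated placeholder; simulations intended to be quantitative
    should supply a fitted set.
    """

    ka: float = 1.0          # absorption rate, 1/h
    cl: float = 1.5          # clearance, L/h/kg
    v1: float = 2.0          # central volume, L/kg
    v2: float = 2.0          # peripheral volume, L/kg
    q: float = 0.5           # inter-compartment clearance, L/h/kg
    f: float = 0.5           # oral bioavailability
    mw_conv: float = DEFAULT_MW_CONV  # μM per mg/L
    lag_h: float = 0.0       # absorption lag time, h

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "v1", "v2", "q", "mw_conv"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PK parameter {name} must be > 0")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"bioavailability f must be in (0, 1], got {self.f!r}")
        if self.lag_h < 0:
            raise ValueError("lag time must be >= 0 h")

    @classmethod
    def from_micro_constants(
        cls, ka: float, k10: float, k12: float, k21: float, v1: float,
        f: float = 1.0, mw_conv: float = DEFAULT_MW_CONV,
    ) -> "PKParams":
        """Build from the micro-rate parameterization (k10, k12, k21)."""
        return cls(
            ka=ka, cl=k10 * v1, v1=v1, q=k12 * v1, v2=k12 * v1 / k21,
            f=f, mw_conv=mw_conv,
        )


@dataclass(frozen=True)
class Regimen:
    """Timed drug doses (mg/kg) and IR fractions (Gy)."""

    drug_doses: tuple = ()
    ir_fractions: tuple = ()

    def __post_init__(self) -> None:
        drug = tuple((float(t), float(a)) for t, a in self.drug_doses)
        ir = tuple((float(t), float(d)) for t, d in self.ir_fractions)
        object.__setattr__(self, "drug_doses", drug)
        object.__setattr__(self, "ir_fractions", ir)
        for name, events in (("drug", drug), ("IR", ir)):
            times = [t for t, _ in events]
            if any(t < 0 for t in times):
                raise ValueError(f"{name} event times must be >= 0 h")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} event times must be strictly increasing")
            if any(a < 0 for _, a in events):
                raise ValueError(f"{name} amounts must be >= 0")

    @property
    def last_event_time(self) -> float:
        times = [t for t, _ in self.drug_doses] + [t for t, _ in self.ir_fractions]
        return max(times) if times else 0.0


def pk_matrix(params: PKParams) -> np.ndarray:
    p = params
    return np.array([
        [-p.ka, 0.0, 0.0],
        [p.ka * p.f, -(p.cl + p.q) / p.v1, p.q / p.v2],
        [0.0, p.q / p.v1, -p.q / p.v2],
    ])


def pk_rhs(amounts: Sequence[float], params: PKParams) -> np.ndarray:
    """Derivatives of (gut, central, peripheral) amounts in mg/kg/h."""
    x = np.asarray(amounts, dtype=float)
    if x.shape != (3,):
        raise ValueError("amounts must be (gut, central, peripheral)")
    if np.any(x < 0):
        raise ValueError("compartment amounts must be >= 0")
    return pk_matrix(params) @ x


def simulate_pk_amounts(
    params: PKParams, regimen: Regimen, times: Sequence[float]
) -> np.ndarray:
    """Amounts (n, 3) at the requested times, exact piecewise propagation."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("output times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("output times must be >= 0 h")

    A = pk_matrix(params)
    dose_at: dict = {}
    for dt_, amt in regimen.drug_doses:
        dose_at[dt_ + params.lag_h] = dose_at.get(dt_ + params.lag_h, 0.0) + amt
    events = sorted(e for e in dose_at if e <= t[-1])

    x = np.zeros(3)
    out = np.empty((len(t), 3))
    cursor = 0.0
    emitted = 0
    if events and events[0] == 0.0:
        x[0] += dose_at.pop(0.0)
        events = events[1:]
    for b in events + [t[-1]]:
        while emitted < len(t) and t[emitted] < b:
            out[emitted] = _propagate_constant(A, x, np.array([t[emitted] - cursor]))[0]
            emitted += 1
        if b > cursor:
            x = _propagate_constant(A, x, np.array([b - cursor]))[0]
            cursor = b
        if b in dose_at:
            x[0] += dose_at.pop(b)
        while emitted < len(t) and t[emitted] == cursor:
            out[emitted] = x
            emitted += 1
    while emitted < len(t):  # times beyond the last event
        out[emitted] = _propagate_constant(A, x, np.array([t[emitted] - cursor]))[0]
        emitted += 1
    return np.clip(out, 0.0, None)


def simulate_pk(params: PKParams, regimen: Regimen, times: Sequence[float]) -> np.ndarray:
    """Plasma concentration (μM) at the requested times under a dosing regimen."""
    amounts = simulate_pk_amounts(params, regimen, times)
    return amounts[:, 1] / params.v1 * params.mw_conv


@dataclass(frozen=True)
class RegimenSpec:
    """Descriptor expanded into an explicit :class:`Regimen`.

    ``drug_days`` / ``ir_days`` are day indices (day 0 starts at t = 0 h);
    the daily drug dose is at the start of the day, a BD regimen adds a
    second dose ``bd_interval_h`` later, and each IR fraction follows that
    day's (first) drug dose by ``ir_lead_h``.
    """

    drug_dose_mg_kg: float = 0.0
    frequency: str = "QD"            # QD | BD
    drug_days: tuple = ()
    ir_dose_gy: float = 0.0
    ir_days: tuple = ()
    ir_lead_h: float = 2.0
    bd_interval_h: float = 12.0

    def __post_init__(self) -> None:
        if self.frequency not in ("QD", "BD"):
            raise ValueError(f"frequency must be QD or BD, got {self.frequency!r}")
        if self.drug_dose_mg_kg < 0 or self.ir_dose_gy < 0:
            raise ValueError("doses must be >= 0")


def build_regimen(spec: RegimenSpec) -> Regimen:
    """Expand a schedule descriptor into explicit, validated event lists."""
    doses = []
    for day in spec.drug_days:
        t0 = 24.0 * day
        doses.append((t0, spec.drug_dose_mg_kg))
        if spec.frequency == "BD":
            doses.append((t0 + spec.bd_interval_h, spec.drug_dose_mg_kg))
    doses.sort()
    times = [t for t, _ in doses]
    if len(set(times)) != len(times):
        raise ValueError("schedule descriptor produces duplicate drug dose times")
    ir = []
    for day in spec.ir_days:
        if spec.drug_dose_mg_kg > 0 and day in spec.drug_days:
            ir.append((24.0 * day + spec.ir_lead_h, spec.ir_dose_gy))
        else:
            ir.append((24.0 * day, spec.ir_dose_gy))
    ir.sort()
    return Regimen(drug_doses=tuple(doses), ir_fractions=tuple(ir))


def radiotherapy_combination(
    drug_dose_mg_kg: float,
    *,
    ir_dose_gy: float = 2.0,
    drug_weeks: int = 3,
    ir_lead_h: float = 2.0,
) -> RegimenSpec:
    """Three weeks of daily drug with two Mon–Fri weeks of daily IR.

    Daily dosing for ``drug_weeks`` weeks (21 doses by default) combined
    with two rounds of five consecutive daily IR fractions (days 0–4 and
    7–11), each fraction ``ir_lead_h`` after that day's oral dose, followed
    by wash-out.
    """
    return RegimenSpec(
        drug_dose_mg_kg=drug_dose_mg_kg,
        frequency="QD",
        drug_days=tuple(range(7 * drug_weeks)),
        ir_dose_gy=ir_dose_gy,
        ir_days=tuple(range(0, 5)) + tuple(range(7, 12)),
        ir_lead_h=ir_lead_h,
    )
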