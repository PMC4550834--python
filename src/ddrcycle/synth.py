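"""Synthetic datasets emulating the in vitro and in vivo study designs.

Each generator simulates the model at known ("true") parameters under a
stated experimental design, then draws independent replicate noise around
the deterministic trajectory:

* γH2AX percentages get additive Gaussian noise (sd in percentage
  points), clipped to [0, 100] with clip events logged;
* cell counts and tumor volumes get multiplicative Gaussian noise
  (coefficient of variation), clipped at 0.

The generating truth is stored in the dataset metadata so a calibration
round-trip can be scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cell_cycle import (
    CellCycleParams,
    ExposureSchedule,
    cycle_seed_state,
    simulate_invitro,
)
from .datasets import Condition, Dataset
from .pk import PKParams, Regimen
from .tumor import TumorParams, simulate_xenograft

logger = logging.getLogger(__name__)

DEFAULT_DOSES_UM = (0.0, 0.3, 1.0, 3.0, 10.0, 30.0)   # 0 = vehicle control
DEFAULT_TIMES_H = (0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0, 60.0, 72.0)
DEFAULT_SEED_CELLS = 100.0


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: ``additive`` (sd in readout units) or ``multiplicative`` (cv)."""

    kind: str = "additive"
    scale: float = 3.0
    n: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"noise kind must be additive or multiplicative, got {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


def default_gamma_noise(n: int = 6) -> NoiseModel:
    """3 percentage points additive, 6 replicates (plate-assay scale)."""
    return NoiseModel(kind="additive", scale=3.0, n=n)


def default_count_noise(n: int = 6) -> NoiseModel:
    """5 % multiplicative, 6 replicates."""
    return NoiseModel(kind="multiplicative", scale=0.05, n=n)


def _draw_replicates(rng: np.random.Generator, truth: np.ndarray, noise: NoiseModel,
                     clip_hi: float | None) -> np.ndarray:
    """(n_rep, len(truth)) noisy draws, clipped to the readout's valid range."""
    if noise.kind == "additive":
        draws = truth[None, :] + rng.normal(0.0, noise.scale, size=(noise.n, len(truth)))
    else:
        draws = truth[None, :] * (1.0 + rng.normal(0.0, noise.scale, size=(noise.n, len(truth))))
    clipped = (draws < 0).sum() + ((draws > clip_hi).sum() if clip_hi is not None else 0)
    if clipped:
        logger.info("clipped %d replicate draws to the valid readout range", int(clipped))
    return np.clip(draws, 0.0, clip_hi)


def _emit_rows(rows: list, cid: str, readout: str, times: np.ndarray,
               draws: np.ndarray) -> None:
    sds = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(draws.shape[1])
    for j, t in enumerate(times):
        for r in range(draws.shape[0]):
            rows.append({
                "condition_id": cid, "readout": readout, "time_h": float(t),
                "value": float(draws[r, j]), "sd": float(sds[j]), "n": draws.shape[0],
            })


def _readout_values(traj, readout: str) -> np.ndarray:
    return {
        "gammaH2AX_pct": traj.gammah2ax_pct,
        "gammaH2AX_ir_pct": traj.gammah2ax_ir_pct,
        "cell_count": traj.total_cells,
    }[readout]


def _generate_invitro(
    true_params: CellCycleParams,
    conditions: dict,
    times: np.ndarray,
    readouts: tuple,
    gamma_noise: NoiseModel,
    count_noise: NoiseModel,
    seed: int,
    design: dict,
) -> Dataset:
    rng = np.random.default_rng(seed)
    rows: list = []
    for cid in sorted(conditions):
        cond = conditions[cid]
        traj = simulate_invitro(cond.initial_state, true_params, cond.schedule, times,
                                solver="expm")
        for readout in readouts:
            truth = _readout_values(traj, readout)
            if readout == "cell_count":
                draws = _draw_replicates(rng, truth, count_noise, clip_hi=None)
            else:
                draws = _draw_replicates(rng, truth, gamma_noise, clip_hi=100.0)
            _emit_rows(rows, cid, readout, times, draws)
    metadata = {
        "true_params": asdict(true_params),
        "seed": int(seed),
        "design": design,
    }
    return Dataset(pd.DataFrame(rows), conditions, metadata)


def generate_dose_response(
    true_params: CellCycleParams,
    doses_um: tuple = DEFAULT_DOSES_UM,
    times_h: tuple = DEFAULT_TIMES_H,
    gamma_noise: NoiseModel | None = None,
    count_noise: NoiseModel | None = None,
    seed: int = 0,
    seed_cells: float = DEFAULT_SEED_CELLS,
) -> Dataset:
    """Concentration–response time course: constant exposure per dose arm.

    Default design: vehicle plus a five-point concentration response
    (0.3–30 μM), 0–72 h sampling, γH2AX % and cell-count readouts, six
    replicates per point.
    """
    gamma_noise = gamma_noise or default_gamma_noise()
    count_noise = count_noise or default_count_noise()
    state0 = cycle_seed_state(seed_cells, true_params)
    conditions = {
        f"dose_{dose:g}uM": Condition(ExposureSchedule.constant(dose), state0)
        for dose in doses_um
    }
    return _generate_invitro(
        true_params, conditions, np.asarray(times_h, dtype=float),
        ("gammaH2AX_pct", "cell_count"), gamma_noise, count_noise, seed,
        design={"kind": "dose_response", "doses_um": list(doses_um)},
    )


def generate_washout(
    true_params: CellCycleParams,
    dose_um: float = 10.0,
    washout_time_h: float = 16.0,
    times_h: tuple = DEFAULT_TIMES_H,
    gamma_noise: NoiseModel | None = None,
    count_noise: NoiseModel | None = None,
    seed: int = 0,
    seed_cells: float = DEFAULT_SEED_CELLS,
) -> Dataset:
    """Wash-out experiment: drug removed at ``washout_time_h``, paired no-wash arm."""
    if washout_time_h <= 0:
        raise ValueError("washout_time_h must be > 0")
    gamma_noise = gamma_noise or default_gamma_noise()
    count_noise = count_noise or default_count_noise()
    state0 = cycle_seed_state(seed_cells, true_params)
    times = np.asarray(times_h, dtype=float)
    if washout_time_h >= times[-1]:
        washout_schedule = ExposureSchedule.constant(dose_um)  # wash-out never observed
    else:
        washout_schedule = ExposureSchedule.washout(dose_um, washout_time_h)
    conditions = {
        "washout": Condition(washout_schedule, state0),
        "no_washout": Condition(ExposureSchedule.constant(dose_um), state0),
    }
    return _generate_invitro(
        true_params, conditions, times,
        ("gammaH2AX_pct", "cell_count"), gamma_noise, count_noise, seed,
        design={"kind": "washout", "dose_um": dose_um, "washout_time_h": washout_time_h},
    )


def generate_ir(
    true_params: CellCycleParams,
    ir_dose_gy: float = 2.0,
    times_h: tuple = DEFAULT_TIMES_H,
    gamma_noise: NoiseModel | None = None,
    count_noise: NoiseModel | None = None,
    seed: int = 0,
    seed_cells: float = DEFAULT_SEED_CELLS,
) -> Dataset:
    """IR exposure at t = 0 with an unirradiated control arm.

    The damage readout is the IR-specific one (IR-compartment fraction),
    matching an assay that quantifies radiation-induced signal over
    background.
    """
    if ir_dose_gy < 0:
        raise ValueError("ir_dose_gy must be >= 0")
    gamma_noise = gamma_noise or default_gamma_noise()
    count_noise = count_noise or default_count_noise()
    state0 = cycle_seed_state(seed_cells, true_params)
    conditions = {
        "ir": Condition(
            ExposureSchedule(segments=((0.0, 0.0),), ir_events=((0.0, ir_dose_gy),)),
            state0,
        ),
        "control": Condition(ExposureSchedule.constant(0.0), state0),
    }
    return _generate_invitro(
        true_params, conditions, np.asarray(times_h, dtype=float),
        ("gammaH2AX_ir_pct", "cell_count"), gamma_noise, count_noise, seed,
        design={"kind": "ir", "ir_dose_gy": ir_dose_gy},
    )


def generate_xenograft(
    true_params: TumorParams,
    pk: PKParams,
    regimens: dict,
    times_h: tuple,
    volume_noise: NoiseModel | None = None,
    gamma_noise: NoiseModel | None = None,
    seed: int = 0,
) -> Dataset:
    """In vivo arms: tumor volume (caliper-style, n=10) and γH2AX (IHC-style, n=5).

    ``regimens`` maps arm name to :class:`~ddrcycle.pk.Regimen`; a vehicle
    arm (empty regimen) is added when absent.
    """
    volume_noise = volume_noise or NoiseModel(kind="multiplicative", scale=0.05, n=10)
    gamma_noise = gamma_noise or NoiseModel(kind="additive", scale=3.0, n=5)
    regimens = dict(regimens)
    if not any(len(r.drug_doses) == 0 and len(r.ir_fractions) == 0 for r in regimens.values()):
        regimens.setdefault("vehicle", Regimen())
    rng = np.random.default_rng(seed)
    times = np.asarray(times_h, dtype=float)
    rows: list = []
    for name in sorted(regimens):
        traj = simulate_xenograft(true_params, pk, regimens[name], times)
        vol_draws = _draw_replicates(rng, traj.volume_cm3, volume_noise, clip_hi=None)
        _emit_rows(rows, name, "tumor_volume", times, vol_draws)
        gamma_draws = _draw_replicates(rng, traj.gammah2ax_pct, gamma_noise, clip_hi=100.0)
        _emit_rows(rows, name, "gammaH2AX_pct", times, gamma_draws)
    metadata = {
        "true_params": {"cycle": asdict(true_params.cycle),
                        "kx": true_params.kx, "shell_coeff": true_params.shell_coeff,
                        "v_cell": true_params.v_cell, "v0": true_params.v0},
        "pk": asdict(pk),
        "seed": int(seed),
        "design": {"kind": "xenograft", "arms": sorted(regimens)},
    }
    # Conditions for in vivo arms are regimen descriptors, not in vitro schedules;
    # store them in metadata and register placeholder schedules for table validity.
    from .cell_cycle import CellCycleState
    conditions = {
        name: Condition(ExposureSchedule.constant(0.0), CellCycleState(g1=1.0))
        for name in regimens
    }
    metadata["regimens"] = {
        name: {"drug_doses": [list(d) for d in r.drug_doses],
               "ir_fractions": [list(d) for d in r.ir_fractions]}
        for name, r in regimens.items()
    }
    return Dataset(pd.DataFrame(rows), conditions, metadata)


def params_from_metadata(metadata: dict) -> CellCycleParams:
    """Rebuild the generating cycle parameters stored by an in vitro generator."""
    return CellCycleParams(**metadata["true_params"])
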