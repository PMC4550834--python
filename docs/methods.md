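# Methods

## The model

`ddrcycle` simulates a population of cycling tumor cells under an ATR
inhibitor and ionizing radiation (IR), at the resolution of cell-cycle
phases rather than intracellular signalling.

**Cell cycle with damage states.** Cells move through G1 → S → G2/M, with
division returning two cells to G1. Replication stress is represented as a
damaged S state (`sd`, the γH2AX-positive population): a fraction `k2` of
cells committing from G1 (rate `k1`) enter `sd` instead of S. Damaged-S
cells are repaired back into S at an ATR-mediated rate, or die at rate
`k4`. The drug inhibits repair hyperbolically,

    repair(C) = k3 · ki / (ki + C),

so the rate is `k3` without drug and halves at `C = ki`. At saturating
drug the rate depends on `k3` and `ki` only through their product — the
root of the identifiability structure discussed below. IR moves a fraction
`1 − exp(−alpha_ir·D)` of every phase instantaneously into arrested
IR-damaged twin compartments, which are repaired (ATM-mediated, rate
`k_ir_repair`, unaffected by the drug) or die (`k_ir_death`). Death is
exit from the population; there is no explicit apoptosis compartment.

For fixed drug concentration the system is linear with constant
coefficients, which gives an exact piecewise matrix-exponential solution
between exposure events. `simulate_invitro` offers that analytic
propagator (`solver="expm"`) next to adaptive LSODA integration (the
default), and the two are cross-checked against each other and against an
independently constructed matrix exponential in the tests.

**Readouts.** The γH2AX-positive percentage is
`100·(z·sd + z_ir·IR)/total`; `z` absorbs assay thresholding differences
(operator-set intensity cutoffs), `z_ir` the same for the IR assay. The
IR experiment is scored with the IR-specific readout
(`100·z_ir·IR/total`), which is identically zero for unirradiated
controls; the combined readout would carry a small replication-stress
background whenever `k2 > 0`. Phase fractions map damaged states onto
their parent phase (S includes `sd` and `sir`).

**PK.** A standard two-compartment oral model in amount space (gut,
central, peripheral; parameters `ka, CL, V1, V2, Q, F`), dosing as
instantaneous gut deposits, concentration `= central/V1 × 1000/MW` (μM).
The model is linear, so dose superposition and `AUC = F·D/CL` hold
exactly and serve as oracles. The default mouse parameter set is an
uncalibrated placeholder; quantitative in vivo work should supply a
fitted set, and human simulations accept external parameter sets.

**Xenograft.** Two copies of the cell-cycle model: a proliferating shell
and a core in which G1 → S commitment is off (cells already in S/G2M
complete the cycle, then rest in G1). The shell capacity is
`Ns* = a·Ntot^(2/3)` — the cell count of a fixed-thickness rim on a
sphere — and a relaxation flux `kx·(Ns − Ns*)` exchanges cells, each
keeping its phase, shell→core above capacity and core→shell when death
depletes the shell. IR fractions hit shell and core alike; drug is
spatially uniform. Volume is total cells × `v_cell`. Cell bookkeeping
(d total/dt = division − death; transfer cancels) is asserted along
trajectories in the tests.

## Default parameters

The study designs this package emulates deposit no public raw data, so
the generator's "true" parameters are the package's own choice of a
realistic ATM-deficient colon-carcinoma line under a potent ATR
inhibitor; they were fixed once as defaults and all tests run against
them.

| parameter | default | unit | rationale |
|---|---|---|---|
| k1 | 0.045 | 1/h | G1 residence ~22 h; overall doubling ~35 h |
| k2 | 0.70 | – | most S entries damaged in a high-replication-stress, ATM-deficient line |
| k3 | 50 | 1/h | untreated repair far faster than any observable process (baseline γH2AX ≪ 1 %) |
| ki | 0.002 | μM | sub-nM effective potency, two decades below the lowest tested dose |
| k4 | 0.15 | 1/h | drug-induced death strong enough that high-dose counts fall, as observed |
| ks | 0.12 | 1/h | S phase ~8 h |
| km | 0.11 | 1/h | G2/M ~9 h |
| k_ir_repair | 0.10 | 1/h | IR signal resolves over ~1 day |
| k_ir_death | 0.03 | 1/h | IR death slower than repair |
| alpha_ir | 0.30 | 1/Gy | ~45 % of cells hit at 2 Gy |
| z | 0.9 | – | thresholding loses some positives |
| z_ir | 1.0 | – | separate scale for the IR assay |

With these values the simulated assay reproduces the qualitative
phenomenology the in vitro studies report: negligible untreated γH2AX
background, a low but clear signal at 0.3 μM, saturation above ~3 μM, a
sustained plateau past 70 h, post-wash-out decay to the control level,
and strong dose-dependent suppression of cell counts. Because `ki` lies
well below the tested concentrations (0.3–30 μM), the data constrain the
product `k3·ki` but not the factors — the deliberate source of the
calibration's known non-identifiability.

## Synthetic data

Generators reproduce the study designs: a vehicle + five-point
concentration response (0.3–30 μM, 0–72 h, γH2AX % and cell count, six
replicates), a 16-h wash-out experiment at 10 μM with a paired
no-wash-out arm, 2 Gy IR with control, and in vivo regimens (QD/BD
multi-day dosing, IR fractions 2 h after the day's dose, tumor volume
n = 10-style and γH2AX IHC n = 5-style arms). Replicate noise is
Gaussian: additive, 3 percentage points, for γH2AX (clipped to [0, 100],
clips logged); multiplicative, 5 % CV, for counts and volumes. The noise
magnitudes are stated defaults resembling plotted error bars, not values
claimed from any source; replicates are independent draws around one
deterministic trajectory, with no batch structure. What passing tests
show is therefore internal consistency of the pipeline under the stated
designs — not robustness to real-data features such as batch effects,
non-Gaussian outliers, plate gradients or model misspecification.

## Calibration

The objective is the plain sum of squared residuals with equal weight
for every observation row, over all conditions and readouts jointly.
Optimization is bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`) over log10 parameters, bounds
±3 decades around nominal (configurable), `k2` capped at 1. Failed
simulations return a finite penalty (1e12) so sweeps complete. The
production `fit` polishes to tight tolerances (1e-12) and is
deterministic given its start.

**Multi-start identifiability.** Starts are sampled log-uniformly and
independently between the bounds; a start counts as converged when its
final objective is within 5 % of the best found. Two numerical choices
matter and are deliberate:

1. *Band-entry stopping.* Each random start optimizes in short bursts
   and stops as soon as it is inside the 5 % band of the best solution
   known so far (a fully polished fit from the nominal start seeds the
   reference, and any start that beats it updates it). The scan's
   purpose is to characterize the set of statistically acceptable
   solutions; when a start enters the band every well-determined
   direction has already converged, while coordinates along any
   effectively-flat ridge still carry the start's sampling. Polishing
   every start to the numerical minimizer instead collapses the whole
   converged cloud onto whichever single point the particular noise
   realization infinitesimally favors, erasing exactly the scatter the
   analysis is meant to reveal.
2. *Spread floor for ranking.* Correlations are computed on log10
   estimates over converged starts. Parameters whose converged spread is
   below 0.1 log10 units (~25 %) are reported as point-identified and
   excluded from correlation *ranking*: with essentially constant
   estimates, sample correlations measure solver round-off, not
   identifiability. The full correlation matrix is still reported.

Under the default study design the scan finds `k3` and `ki` scattered
over decades with correlation ≈ −1 (the product ridge) and every other
parameter point-identified — the expected structure given that `ki` is
far below the tested doses.

**Goodness of fit.** `r_squared_slope1` implements the parity-plot
statistic: a least-squares fit of observed = predicted + b with the slope
fixed at 1, scored as `1 − SSres/SStot` about the observed mean. A
constant offset scores 1; the statistic is ≤ 1 and is undefined for
constant observations.

## Numerical choices

* Integrators: LSODA with rtol 1e-8, atol 1e-10 (in vitro) and a scaled
  atol for the 17-state joint PK-tumor system (1e-12 on PK amounts, 1e-3
  cells on compartments holding ~1e8 cells). Calibration uses the exact
  matrix-exponential path.
* Dose, wash-out and IR events are integration breakpoints; the state
  reported at an event time is the post-event state.
* Output states are clipped at zero; undershoot beyond 1e-6 cells logs a
  warning.
* Seed populations are distributed over G1/S/G2M according to the
  dominant eigenvector of the damage-free cycle matrix, so simulations
  start in balanced growth; the xenograft seed puts the shell at
  capacity and the core at rest in G1.
* Problem sizes in the test suite and acceptance script — 20 recovery
  seeds, 200 multistart starts, 28-day xenograft horizons at 12–24 h
  output resolution — are the package's desk-scale defaults; the
  multistart count is configurable up to the 3,000 used in full-scale
  analyses.

## Known limitations

* Several structural choices have no external reference implementation
  to check against line-by-line; the closures above (cycle progression
  rates, single-hit IR fraction, surface-area shell capacity, relaxation
  transfer) are this package's documented choices and reproduce the
  intended phenomenology.
* No spatial structure beyond shell/core: no drug penetration gradient,
  vasculature, hypoxia or immune compartment; no toxicity model.
* The in vivo PK defaults are placeholders; nothing in the repository
  calibrates them.
* Death is memoryless exit; cell-fate detail (arrest vs apoptosis vs
  mitotic catastrophe) is abstracted into `k4` and `k_ir_death`.
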