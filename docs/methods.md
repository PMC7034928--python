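# Methods

## Model overview

`emp-popsim` couples a deterministic intracellular circuit to a stochastic
birth–death population process.

**Intracellular circuit.** Each cell carries the core regulatory circuit of
epithelial–mesenchymal plasticity (EMP): two coupled mutually-inhibitory
modules, miR-200 ⊣ ZEB (with ZEB self-activation) and miR-34 ⊣ SNAIL, with
SNAIL activating ZEB transcription and repressing both microRNAs.  A lumped
EMT-inducing signal `Isig` (molecules/cell) drives SNAIL transcription
through a shifted Hill function and is the bifurcation parameter.
MicroRNA–mRNA interactions use combinatorial binding (six miR-200 sites on
ZEB mRNA, two miR-34 sites on SNAIL mRNA) with per-occupancy translation
silencing and degradation weights.  Over a window of `Isig` the circuit is
tri-stable; the three stable branches map onto the epithelial (E), hybrid
E/M (H) and mesenchymal (M) phenotypes, classified by ZEB mRNA copy number.

With the default kinetic parameters (`params.py`, all rates per hour, all
copy numbers per cell) the branch structure over `Isig` is

| branch | exists on (molecules/cell) |
|--------|---------------------------|
| E | [0, ≈5.48·10⁴] |
| H | [≈4.78·10⁴, ≈5.77·10⁴] |
| M | [≈3.88·10⁴, ∞) |

so the stable-state count sweeps 1 → 2 → 3 → 2 → 1 as the signal rises.

**Quasi-steady-state assumption.** Cells do not integrate the circuit
between divisions: intracellular relaxation (hours) is treated as fast
relative to the cell cycle (∼38 h), so a cell's state is fully determined
by its branch label and signal level.  Division-time perturbations are the
only source of phenotype change.

**Partitioning noise.** At division, a daughter's signal is the parent's
plus additive Gaussian noise of standard deviation η (molecules/cell),
truncated at zero (truncation, not resampling: a signal at zero is treated
as an absorbing boundary of the coarse-grained model).  The daughter
relaxes from the inherited circuit state at its new signal level: it stays
on the parent's branch where that branch still exists, and otherwise falls
to the attractor reached by ODE relaxation from the vanished branch's
endpoint, which is precomputed per saddle-node ("fall-off maps").

**Partition conventions.** Two conventions relate daughters to the parent:

* `birth` (default): a division is a Gillespie birth event — one daughter
  continues with the parent's signal level, the newborn receives the noisy
  partition.  One independent Gaussian draw per division.
* `symmetric`: both daughters receive independent noisy partitions (two
  draws per division).

The default is the `birth` convention.  The package's division-outcome
statistics and composition timescales are calibrated under it; under the
`symmetric` convention every phenotype-switch probability roughly doubles,
because two daughters are perturbed per division instead of one.  The
convention is a `NoiseSpec` field and all partitioning operations support
both.

**Population process.** Exact (direct-method) Gillespie simulation with
per-phenotype aggregated propensities: division at `b_φ (1 − N/K)` (floored
at zero at the carrying capacity) and death at fixed `d_φ`.  The logistic
factor applies to division only, keeping death a fixed rate.  The total
count therefore follows a logistic with growth rate `b − d` and stationary
size `K(1 − d/b)` in the mean-field limit; near saturation the stochastic
mean sits O(1/K) below the deterministic curve, which the tests allow for.

## Parameters that matter

| parameter | units | default | rationale |
|-----------|-------|---------|-----------|
| η (Isig partition SD) | molecules/cell | 2.7·10⁴ | best-fit noise for the murine prostate time courses; the ratio to the mean signal of dividing cells is ≈0.4 |
| doubling time T_d | h | 38.0 | typical cancer-cell doubling time; division rate b = ln2/T_d (a mean-waiting-time reading b = 1/T_d is a config switch) |
| death rate d | 1/h | 0.005 | not independently constrained; chosen so the stationary size stays close to K while divisions persist at stationarity (turnover ≈ 1 division/cell per 8 days). Division-outcome probabilities are insensitive to d over [5·10⁻⁴, 10⁻²] |
| carrying capacity K | cells | 10000 | population cap of the logistic model |
| initial signal | — | log-normal, median 2·10⁴, CV 1.0 | right-skewed signal abundance across an epithelium-derived population; places ≈88% of cells on the E branch |
| cv_species | — | 0 (0.25 in all-species mode) | multiplicative partitioning noise on every circuit species |

## Stabilizer variants (GRHL2, ΔNP63α)

Both variants append a species X in mutual inhibition with ZEB
(ZEB ⊣ X transcription, X ⊣ ZEB-mRNA transcription).  Their kinetic
constants are **calibrated, not transcribed**: no complete published
parameterization was available to this package, so the coupling strengths
were chosen once so that (i) the hybrid branch interval widens severalfold
(core ≈0.99·10⁴ < GRHL2 ≈7.6·10⁴ < ΔNP63α ≈1.28·10⁵ molecules), and
(ii) a pure-hybrid population retains the hybrid fraction on the scale the
modulator literature reports (≈37% at day 14 for GRHL2, >50% for ΔNP63α).
The frozen values sit in `params.grhl2_params()` / `params.dnp63a_params()`.

## Protocols

**Hysteresis dosing.** A fixed dose is added daily for 10 days, then
withdrawn daily for 10 days (clamped at zero).  The default dose is
`(multistable span + margin)/10` with margin 8·10⁴, sized so ten additions
push essentially every cell past the upper saddle despite the Gaussian
spreading the division noise adds along the way.

**RA/TGF-β co-treatment.** Retinoic acid contributes an inhibitory
shifted-Hill factor on SNAIL-mRNA production (λ = 0.1, half-effect 1 μM,
n = 2), exogenous TGF-β an activating one (λ = 10, half-effect 0.3 ng/ml,
n = 1).  The half-effect concentrations are calibrated to three anchors:
5 μM RA caps the SNAIL drive below the range where H or M exist (EMT
blocked; the treated circuit is monostable E), 5 μM + 5 ng/ml gives a net
factor ≈1.27 (the block is abrogated), and 5 μM + 0.5 ng/ml gives ≈0.85,
which shifts and stretches the hybrid window (partial-EMT regime).  Treated
circuits can lose branches; their tables are labelled against the untreated
circuit's classification cutoffs.

**Drug regimens.** A drug multiplies the death rate of targeted phenotypes
by a shifted Hill function of concentration (default half-effect 10⁴ units,
n = 2, saturation ×20, i.e. 0.1/h against a division rate of 0.018/h).
Untargeted phenotypes are unaffected.

## Numerical choices

* **Steady states.** Multi-start Newton (hybr) from deterministic archetype
  guesses plus continuation seeds, with a relaxation fallback when no root
  converges; stability via eigenvalues of a finite-difference Jacobian;
  duplicates merged at relative tolerance 10⁻⁶.
* **Bifurcation table.** Branch families stitched across the grid by
  nearest-state matching on (log ZEB mRNA, log ZEB); single-point dropouts
  repaired by continuation; saddle-nodes refined by bisection on branch
  existence to relative precision 10⁻⁶.  Fall-off outcome boundaries are
  bisected and then snapped to coinciding saddle-node positions so interval
  membership and fall-off lookups can never disagree.
* **Phenotype cutoffs.** Derived per table as midpoints between the ZEB-mRNA
  ranges of adjacent branches (E max↔H min, H max↔M min), not hard-coded;
  classification is therefore robust to solver tolerance.
* **Relaxation.** LSODA in 400 h chunks until the scaled residual
  `max |ẏᵢ|/(1+|yᵢ|) < 10⁻⁶`; used for daughter-cell settling in the oracle
  path, the fall-off precomputation, and the all-species / asymmetric
  miR-34a modes.
* **Asymmetric miR-34a division.** During hybrid division one daughter
  (fair coin) gets zero miR-34a; the other keeps the parent concentration
  (`zero-one`) or twice it (`zero-double`).  The perturbed daughter's
  outcome is precomputed by relaxation on the table grid and cached; the
  two bookkeeping modes give statistically indistinguishable population
  trajectories.
* **Reproducibility.** One master seed per run; replicate seeds spawned via
  `SeedSequence`; identical (seed, config) gives identical trajectories and
  event logs.  Protocol events are merged with the reaction clock (the
  waiting time is redrawn at each boundary, valid by memorylessness).

## What the generator emulates — and what it does not

The synthetic populations emulate: logistic growth to a fixed capacity with
phenotype-independent (by default) rates; spontaneous composition drift
from division noise alone; sorting experiments (pure-phenotype initial
conditions rejection-sampled from the same log-normal); dosing, modulator
and drug protocols.  They do **not** emulate: cell–cell communication or
spatial structure, continuous intracellular stochasticity between
divisions, epigenetic or autocrine feedback, drug resistance evolution, or
measurement noise in cytometry gating.  Passing tests therefore show that
the division-noise mechanism reproduces the published population
statistics under these idealizations, not that it is the mechanism in any
particular experimental system.

A specific consequence of the idealized sorting: rejection-sampling the
day-0 log-normal concentrates pure-M populations just above the
mesenchymal saddle, where early divisions shed daughters to E at a higher
rate than a long-cultured (upward-drifted) mesenchymal population would;
day-14 mesenchymal retention is correspondingly conservative.  See the
decisions of the test suite for where this matters.

## Problem sizes

Default desk scale for stochastic checks: 8 replicates, carrying capacity
5000 (tests) or 10000 (acceptance script), 14-day horizons for sorted
dynamics and 8-week horizons for division tallies.  The oracle-equivalence
check compares the table lookup against full ODE relaxation on 10⁴ sampled
division events.
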