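"""Time-structured interventions and experiment runners.

Hysteresis dosing (daily addition/withdrawal of the EMT-inducing signal),
retinoic-acid / TGF-beta co-treatment (mapped to fold-changes on SNAIL
transcription), phenotype-targeted drug regimens (shifted-Hill death-rate
multipliers) and the seeded replicate runner with RMSD parameter fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bifurcation import BranchTable
from .circuit import shifted_hill
from .params import CircuitParams
from .partitioning import NoiseSpec
from .population import (
    PHENOTYPES,
    DivisionRecord,
    Population,
    RateSpec,
    Trajectory,
    init_population,
    simulate,
)

__all__ = [
    "DoseEvent",
    "DrugRegimen",
    "ExogenousInputs",
    "Protocol",
    "apply_dose",
    "drug_multiplier",
    "run_treatment",
    "apply_exogenous_inputs",
    "hysteresis_protocol",
    "default_dose",
    "run_replicates",
    "ReplicateSummary",
    "fit_parameter",
]


@dataclass(frozen=True)
class DoseEvent:
    """An instantaneous signed shift of every living cell's signal level."""

    time: float  # hours from simulation start
    d_isig: float  # molecules/cell; negative withdraws


@dataclass(frozen=True)
class DrugRegimen:
    """Phenotype-targeted drug as a multiplicative death-rate factor.

    The multiplier on targeted phenotypes is the shifted Hill function of
    the drug concentration (1 at zero concentration, saturating at
    ``lam_d > 1``); untargeted phenotypes are unaffected.
    """

    targets: frozenset[str]
    concentration: float
    d0: float = 1.0e4  # half-effect concentration, arbitrary units
    n_d: int = 2
    lam_d: float = 20.0
    duration_days: float = 28.0

    def __post_init__(self) -> None:
        bad = set(self.targets) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown target phenotypes {bad}")
        if self.lam_d <= 1:
            raise ValueError("drug fold-change lam_d must exceed 1")
        if self.concentration < 0:
            raise ValueError("drug concentration must be >= 0")


@dataclass(frozen=True)
class ExogenousInputs:
    """RA / TGF-beta co-treatment mapped onto SNAIL-mRNA production.

    Retinoic acid (an MET inducer) contributes an inhibitory shifted-Hill
    factor, exogenous TGF-beta (an EMT inducer) an activating one; the
    half-effect concentrations are calibrated anchors (docs/methods.md).
    Zero concentrations leave the parameters unchanged.
    """

    ra_um: float = 0.0
    tgfb_ng_ml: float = 0.0
    ra_half_um: float = 1.0
    ra_n: int = 2
    ra_lam: float = 0.1
    tgfb_half_ng_ml: float = 0.3
    tgfb_n: int = 1
    tgfb_lam: float = 10.0

    def factor(self) -> float:
        f = 1.0
        if self.ra_um > 0:
            f *= shifted_hill(self.ra_um, self.ra_half_um, self.ra_n, self.ra_lam)
        if self.tgfb_ng_ml > 0:
            f *= shifted_hill(
                self.tgfb_ng_ml, self.tgfb_half_ng_ml, self.tgfb_n, self.tgfb_lam
            )
        return f


@dataclass
class Protocol:
    """Ordered dose events plus optional drug regimen and co-treatment."""

    doses: list[DoseEvent] = field(default_factory=list)
    drug: DrugRegimen | None = None
    exogenous: ExogenousInputs | None = None

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda e: e.time)

    # interface consumed by population.simulate -------------------------

    def hooks(self, pop: Population, t0: float):
        return [
            (t0 + e.time, (lambda ev=e: apply_dose(pop, ev, pop.table)))
            for e in self.doses
        ]

    def death_multipliers(self, rel_time: float) -> dict[str, float]:
        if self.drug is None or rel_time >= self.drug.duration_days * 24.0:
            return {}
        return {k: drug_multiplier(self.drug, k) for k in self.drug.targets}


def apply_dose(pop: Population, event: DoseEvent, table: BranchTable) -> Population:
    """Shift every cell's signal by ``d_isig`` (clamped at 0) and re-settle.

    Each cell keeps its branch where the branch still exists at the new
    level, otherwise falls off through the table's relaxation map.
    """
    moved: list[tuple[str, float, int, float, int]] = []
    for br in PHENOTYPES:
        vals = pop._isig[br]
        j = 0
        while j < len(vals):
            x = max(0.0, vals[j] + event.d_isig)
            nb = table.transition(br, x)
            if nb == br:
                vals[j] = x
                j += 1
            else:
                isg, cid, birth, parent, inputs = pop._pop_cell(br, j)
                moved.append((nb, x, cid, birth, parent))
    for nb, x, cid, birth, parent in moved:
        pop._isig[nb].append(x)
        pop._id[nb].append(cid)
        pop._birth[nb].append(birth)
        pop._parent[nb].append(parent)
    return pop


def drug_multiplier(regimen: DrugRegimen, phenotype: str) -> float:
    """Death-rate multiplier for one phenotype under the regimen."""
    if phenotype not in regimen.targets:
        return 1.0
    return float(
        shifted_hill(regimen.concentration, regimen.d0, regimen.n_d, regimen.lam_d)
    )


def run_treatment(pop: Population, regimen: DrugRegimen, duration_days: float,
                  rng: np.random.Generator,
                  sample_interval: float = 24.0):
    """Treat an established population and report growth and composition.

    Returns ``(percent change in cell number, final fractions, trajectory)``.
    """
    n_start = pop.size
    protocol = Protocol(drug=replace(regimen, duration_days=duration_days))
    traj, _ = simulate(pop, duration_days * 24.0, protocol, sample_interval, rng)
    n_end = pop.size
    pct = 100.0 * (n_end - n_start) / n_start
    return pct, pop.fractions(), traj


def apply_exogenous_inputs(p: CircuitParams, x: ExogenousInputs) -> CircuitParams:
    """Parameter set under RA / TGF-beta co-treatment."""
    if x.ra_um < 0 or x.tgfb_ng_ml < 0:
        raise ValueError("concentrations must be >= 0")
    f = x.factor()
    if f == 1.0:
        return p
    return p.with_production_factor(p.snail_mrna_production_factor * f)


def default_dose(table: BranchTable, margin: float = 8.0e4) -> float:
    """Daily hysteresis dose: a tenth of the multistable span plus margin.

    Sized so that ten daily additions carry a typical cell across the
    entire multistable window and past the upper saddle-node.
    """
    saddles = [br.lo for br in table.branches.values() if br.lo > table.grid[0]]
    saddles += [br.hi for br in table.branches.values() if np.isfinite(br.hi)]
    return (max(saddles) - min(saddles) + margin) / 10.0


def hysteresis_protocol(table: BranchTable, dose: float | None = None,
                        n_up: int = 10, n_down: int = 10) -> Protocol:
    """Daily signal additions for ``n_up`` days, then daily withdrawals."""
    if dose is None:
        dose = default_dose(table)
    events = [DoseEvent(24.0 * k, dose) for k in range(n_up)]
    events += [DoseEvent(24.0 * (n_up + k), -dose) for k in range(n_down)]
    return Protocol(doses=events)


# ---------------------------------------------------------------------------
# replicate runner and RMSD fitting


@dataclass
class ReplicateSummary:
    """Pointwise mean and SD of fractions and counts across seeded runs."""

    times: np.ndarray  # hours
    mean_fractions: dict[str, np.ndarray]
    sd_fractions: dict[str, np.ndarray]
    mean_total: np.ndarray
    sd_total: np.ndarray
    trajectories: list[Trajectory]
    records: list[list[DivisionRecord]]

    def at_day(self, day: float) -> dict[str, float]:
        j = int(np.argmin(np.abs(self.times - day * 24.0)))
        return {k: float(self.mean_fractions[k][j]) for k in PHENOTYPES}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for k in PHENOTYPES:
            df[f"frac_{k}_mean"] = self.mean_fractions[k]
            df[f"frac_{k}_sd"] = self.sd_fractions[k]
        df["n_total_mean"] = self.mean_total
        df["n_total_sd"] = self.sd_total
        return df


def run_replicates(table: BranchTable, n_runs: int, base_seed: int,
                   init_mode: str = "lognormal-mix", n0: int = 500,
                   duration_days: float = 14.0,
                   rates: RateSpec | None = None,
                   noise: NoiseSpec | None = None,
                   protocol_factory=None,
                   median: float = 2.0e4, cv: float = 1.0,
                   sample_interval: float = 24.0) -> ReplicateSummary:
    """Run ``n_runs`` independent seeded simulations and summarize.

    ``protocol_factory``, if given, is called once per replicate (the
    protocol's hooks bind to that replicate's population).  Replicate seeds
    are spawned deterministically from ``base_seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rates = rates or RateSpec()
    noise = noise or NoiseSpec()
    trajectories, all_records = [], []
    seeds = np.random.SeedSequence(base_seed).spawn(n_runs)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        pop = init_population(n0, init_mode, table, rng, median, cv, rates, noise)
        protocol = None if protocol_factory is None else protocol_factory(pop)
        traj, recs = simulate(pop, duration_days * 24.0, protocol,
                              sample_interval, rng)
        trajectories.append(traj)
        all_records.append(recs)

    n_t = min(len(tr.times) for tr in trajectories)
    times = trajectories[0].times[:n_t]
    fr = {
        k: np.vstack([tr.fractions()[k][:n_t] for tr in trajectories])
        for k in PHENOTYPES
    }
    tot = np.vstack([tr.total[:n_t] for tr in trajectories])
    return ReplicateSummary(
        times,
        {k: fr[k].mean(axis=0) for k in PHENOTYPES},
        {k: fr[k].std(axis=0, ddof=0) for k in PHENOTYPES},
        tot.mean(axis=0),
        tot.std(axis=0, ddof=0),
        trajectories,
        all_records,
    )


_INIT_BY_NAME = {"pure-E": "pure-E", "pure-H": "pure-H", "pure-M": "pure-M"}


def fit_parameter(reference: pd.DataFrame, grid, which: str,
                  table_factory, base_seed: int = 0, n_runs: int = 8,
                  n0: int = 500, rates: RateSpec | None = None,
                  noise: NoiseSpec | None = None):
    """Grid-search ``eta`` or the doubling time against reference fractions.

    ``reference`` has columns ``day, frac_E, frac_H, frac_M,
    initial_condition`` covering the three sorted-population experiments
    (pure-E / pure-H / pure-M starts).  For every grid value the three
    experiments are simulated, squared deviations of the simulated mean
    fractions from the reference are pooled over phenotypes, time points
    and initial conditions, and the root mean square reported.  Returns
    ``(best value, DataFrame of RMSD vs parameter)``.

    ``table_factory()`` supplies the (shared) branch table; a fresh
    :class:`RateSpec`/:class:`NoiseSpec` is derived per grid value.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if which not in ("eta", "doubling_time"):
        raise ValueError("which must be 'eta' or 'doubling_time'")
    required = {"day", "frac_E", "frac_H", "frac_M", "initial_condition"}
    if not required.issubset(reference.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    conds = sorted(set(reference["initial_condition"]))
    unknown = set(conds) - set(_INIT_BY_NAME)
    if unknown:
        raise ValueError(f"unknown initial conditions {unknown}")
    rates = rates or RateSpec()
    noise = noise or NoiseSpec()
    table = table_factory()
    horizon = float(reference["day"].max())

    rows = []
    for value in grid:
        r = rates if which == "eta" else replace(rates, doubling_time=float(value))
        ns = replace(noise, eta=float(value)) if which == "eta" else noise
        sq = []
        for ci, cond in enumerate(conds):
            summ = run_replicates(
                table, n_runs, base_seed + 1000 * (ci + 1),
                init_mode=_INIT_BY_NAME[cond], n0=n0,
                duration_days=horizon, rates=r, noise=ns,
            )
            sub = reference[reference["initial_condition"] == cond]
            for _, row in sub.iterrows():
                sim = summ.at_day(float(row["day"]))
                for k in PHENOTYPES:
                    sq.append((sim[k] - float(row[f"frac_{k}"])) ** 2)
        rows.append({"value": float(value), "rmsd": math.sqrt(np.mean(sq))})
    curve = pd.DataFrame(rows)
    best = float(curve.loc[curve["rmsd"].idxmin(), "value"])
    return best, curve
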