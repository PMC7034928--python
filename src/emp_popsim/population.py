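"""Stochastic birth-death population dynamics of EMP-plastic cells.

Exact (Gillespie) simulation of a well-mixed population under logistic
competition: every cell divides with propensity ``b_phi (1 - N/K)`` and
dies at fixed rate ``d_phi``, where ``phi`` is its phenotype.  A division
replaces the parent by two daughters whose signal levels come from the
partitioning-noise model and whose phenotypes follow from the bifurcation
table (branch persistence, or the precomputed relaxation fall-off when the
parent's branch no longer exists at the daughter's signal level).

Cells do not integrate their circuit between divisions: the intracellular
dynamics are assumed fast relative to the cell cycle, so a cell sits on a
stable branch fully determined by (branch label, signal level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .bifurcation import BranchTable
from .circuit import relax_to_steady_state
from .partitioning import NoiseSpec, partition_all_species, partition_inputs, partition_isig

__all__ = [
    "PHENOTYPES",
    "RateSpec",
    "Cell",
    "Population",
    "DivisionRecord",
    "Trajectory",
    "init_population",
    "divide_cell",
    "simulate",
    "tally_divisions",
]

PHENOTYPES = ("E", "H", "M")

LN2 = math.log(2.0)


def _per_phenotype(value) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(PHENOTYPES) - set(value)
        if missing:
            raise ValueError(f"missing phenotypes in rate mapping: {missing}")
        return {k: float(value[k]) for k in PHENOTYPES}
    return {k: float(value) for k in PHENOTYPES}


@dataclass(frozen=True)
class RateSpec:
    """Per-phenotype growth/death rates and the carrying capacity.

    ``doubling_time`` (hours) sets the division rate ``b = ln 2 / T_d`` in
    the no-competition, no-death limit; with ``mean_waiting_time=True`` the
    alternative reading ``b = 1 / T_d`` (mean inter-division interval) is
    used instead.  ``death_rate`` is 1/h.  Scalars apply to all phenotypes.
    """

    doubling_time: float | dict = 38.0
    death_rate: float | dict = 0.005
    carrying_capacity: int = 10000
    mean_waiting_time: bool = False

    def __post_init__(self) -> None:
        td = _per_phenotype(self.doubling_time)
        d = _per_phenotype(self.death_rate)
        if any(v <= 0 for v in td.values()) or any(v < 0 for v in d.values()):
            raise ValueError("doubling times must be > 0, death rates >= 0")
        if self.carrying_capacity < 1:
            raise ValueError("carrying capacity must be >= 1")
        for k in PHENOTYPES:
            if self.division_rate(k) <= d[k]:
                raise ValueError(
                    f"division rate must exceed death rate for {k} "
                    f"(b={self.division_rate(k):.4g}, d={d[k]:.4g})"
                )

    def division_rate(self, phenotype: str) -> float:
        td = _per_phenotype(self.doubling_time)[phenotype]
        return (1.0 / td) if self.mean_waiting_time else (LN2 / td)

    def death(self, phenotype: str) -> float:
        return _per_phenotype(self.death_rate)[phenotype]


@dataclass(frozen=True)
class Cell:
    """One cell: signal level, branch identity and lineage metadata."""

    id: int
    isig: float
    branch: str
    birth_time: float = 0.0
    parent_id: int = -1
    inputs: np.ndarray | None = None

    @property
    def phenotype(self) -> str:
        return self.branch

    def state(self, table: BranchTable) -> np.ndarray:
        """Circuit steady state implied by (branch, signal level)."""
        return table.state_of(self.branch, self.isig)


class DivisionRecord(NamedTuple):
    """Phenotype log of one division: parent and its two daughters."""

    time: float
    parent: str
    daughter1: str
    daughter2: str


@dataclass
class Trajectory:
    """Time-sampled phenotype counts of one simulation run."""

    times: np.ndarray
    counts: dict[str, np.ndarray]
    n_divisions: np.ndarray  # cumulative at each sample
    n_deaths: np.ndarray
    extinct: bool = False

    @property
    def total(self) -> np.ndarray:
        return sum(self.counts[k] for k in PHENOTYPES)

    def fractions(self) -> dict[str, np.ndarray]:
        tot = np.maximum(self.total, 1)
        return {k: self.counts[k] / tot for k in PHENOTYPES}

    def at_day(self, day: float) -> dict[str, float]:
        """Phenotype fractions at the sample nearest to ``day`` (days)."""
        j = int(np.argmin(np.abs(self.times - day * 24.0)))
        fr = self.fractions()
        return {k: float(fr[k][j]) for k in PHENOTYPES}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for k in PHENOTYPES:
            df[f"n_{k}"] = self.counts[k]
        df["n_total"] = self.total
        return df


class Population:
    """Living cells plus their rate and noise specifications.

    Cells are stored per branch as parallel lists (signal level, id, birth
    time, parent id) for O(1) Gillespie event selection; :meth:`cells`
    materializes :class:`Cell` views on demand.
    """

    def __init__(self, table: BranchTable, rates: RateSpec, noise: NoiseSpec):
        self.table = table
        self.rates = rates
        self.noise = noise
        self.clock = 0.0
        self._isig: dict[str, list[float]] = {k: [] for k in PHENOTYPES}
        self._id: dict[str, list[int]] = {k: [] for k in PHENOTYPES}
        self._birth: dict[str, list[float]] = {k: [] for k in PHENOTYPES}
        self._parent: dict[str, list[int]] = {k: [] for k in PHENOTYPES}
        self._inputs: dict[str, list[np.ndarray]] | None = None
        self._next_id = 0

    # -- bookkeeping -----------------------------------------------------

    @property
    def multi_input(self) -> bool:
        return self._inputs is not None

    def enable_inputs(self) -> None:
        self._inputs = {k: [] for k in PHENOTYPES}

    def add_cell(self, branch: str, isig: float, birth_time: float = 0.0,
                 parent_id: int = -1, inputs: np.ndarray | None = None) -> int:
        cid = self._next_id
        self._next_id += 1
        self._isig[branch].append(isig)
        self._id[branch].append(cid)
        self._birth[branch].append(birth_time)
        self._parent[branch].append(parent_id)
        if self._inputs is not None:
            self._inputs[branch].append(np.asarray(inputs, dtype=float))
        return cid

    def _pop_cell(self, branch: str, idx: int):
        """Remove and return (isig, id, birth, parent, inputs) by swap-pop."""
        out = []
        lists = [self._isig[branch], self._id[branch], self._birth[branch],
                 self._parent[branch]]
        if self._inputs is not None:
            lists.append(self._inputs[branch])
        for lst in lists:
            val = lst[idx]
            lst[idx] = lst[-1]
            lst.pop()
            out.append(val)
        if self._inputs is None:
            out.append(None)
        return out

    @property
    def size(self) -> int:
        return sum(len(v) for v in self._isig.values())

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._isig.items()}

    def fractions(self) -> dict[str, float]:
        n = self.counts()
        tot = max(1, sum(n.values()))
        return {k: v / tot for k, v in n.items()}

    def cells(self) -> Iterator[Cell]:
        for br in PHENOTYPES:
            for j in range(len(self._isig[br])):
                yield Cell(
                    self._id[br][j], self._isig[br][j], br,
                    self._birth[br][j], self._parent[br][j],
                    None if self._inputs is None else self._inputs[br][j],
                )

    def isig_values(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v) for k, v in self._isig.items()}


def init_population(n: int, mode: str, table: BranchTable,
                    rng: np.random.Generator,
                    median: float = 2.0e4, cv: float = 1.0,
                    rates: RateSpec | None = None,
                    noise: NoiseSpec | None = None,
                    max_attempts: int = 10_000_000) -> Population:
    """Seed a population with log-normally distributed signal levels.

    ``mode="lognormal-mix"`` models an epithelium-derived line: each cell
    is placed on the E branch where it exists, else H, else M.  ``pure-E`` /
    ``pure-H`` / ``pure-M`` rejection-sample the same log-normal until the
    requested branch exists at the drawn level.  ``cv=0`` degenerates to
    all cells at the median.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if mode not in ("lognormal-mix", "pure-E", "pure-H", "pure-M"):
        raise ValueError(f"unknown init mode {mode!r}")
    rates = rates or RateSpec()
    noise = noise or NoiseSpec()
    pop = Population(table, rates, noise)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    want = mode[5:] if mode.startswith("pure-") else None
    if want is not None and want not in table.branches:
        raise RuntimeError(f"branch {want} does not exist in this circuit's table")
    attempts = 0
    while pop.size < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection sampling failed: branch {want} incompatible with "
                f"log-normal(median={median}, cv={cv})"
            )
        x = median * math.exp(sigma * rng.standard_normal()) if sigma else median
        if want is None:
            for br in PHENOTYPES:  # E first: epithelium-derived population
                if br in table.branches and table.branches[br].contains(x):
                    pop.add_cell(br, x)
                    break
        elif table.branches[want].contains(x):
            pop.add_cell(want, x)
    return pop


# ---------------------------------------------------------------------------
# division


def _daughter_fates(branch: str, isig: float, noise: NoiseSpec,
                    table: BranchTable, rng: np.random.Generator,
                    oracle: bool = False) -> list[tuple[float, str]]:
    """(signal level, branch) of both daughters of a dividing cell.

    The fast path resolves branches through the table
    (:meth:`BranchTable.transition` and the cached miR-34a outcome maps);
    ``oracle=True`` relaxes the full ODEs instead (slow; used for
    verification).
    """
    if noise.convention == "birth":
        z = rng.standard_normal()
        x1, x2 = isig, max(0.0, isig + noise.eta * z)
    else:
        x1, x2 = partition_isig(isig, noise, rng)

    mir34 = noise.mir34_mode != "off" and branch == "H"
    if noise.cv_species > 0 or (mir34 and oracle):
        return _daughter_fates_state(branch, isig, (x1, x2), noise, table, rng, oracle)

    fates = []
    depleted = rng.random() < 0.5 if mir34 else None
    for j, x in enumerate((x1, x2)):
        if mir34:
            if depleted == (j == 0):
                fates.append((x, table.mir34_outcome("depleted", x)))
                continue
            if noise.mir34_mode == "zero-double":
                fates.append((x, table.mir34_outcome("doubled", x)))
                continue
        if oracle:
            final = relax_to_steady_state(
                table.state_of(branch, isig), _isig_arg(table, x),
                table.params, drive=_drive_arg(table, x))
            fates.append((x, table._nearest_label(final, x)))
        else:
            fates.append((x, table.transition(branch, x)))
    return fates


def _isig_arg(table, x):
    return x if table.axis == "isig" else 0.0


def _drive_arg(table, x):
    return x if table.axis == "drive" else None


def _daughter_fates_state(branch, isig, xs, noise, table, rng, oracle):
    """Full-state path: species-level noise requires per-daughter relaxation."""
    parent_state = table.state_of(branch, isig)
    if noise.cv_species > 0:
        s1, s2 = partition_all_species(parent_state, noise, rng)
    else:
        s1, s2 = parent_state.copy(), parent_state.copy()
    if noise.mir34_mode != "off" and branch == "H":
        from .circuit import I_MIR34

        factor = 1.0 if noise.mir34_mode == "zero-one" else 2.0
        if rng.random() < 0.5:
            s1[I_MIR34], s2[I_MIR34] = 0.0, s2[I_MIR34] * factor
        else:
            s2[I_MIR34], s1[I_MIR34] = 0.0, s1[I_MIR34] * factor
    fates = []
    for x, s in zip(xs, (s1, s2)):
        final = relax_to_steady_state(s, _isig_arg(table, x), table.params,
                                      drive=_drive_arg(table, x))
        fates.append((x, table._nearest_label(final, x)))
    return fates


def divide_cell(parent: Cell, noise: NoiseSpec, table: BranchTable,
                rng: np.random.Generator, oracle: bool = False,
                time: float = 0.0) -> tuple[Cell, Cell]:
    """Replace a parent by two daughters with partitioned signal levels.

    Daughters inherit the parent's circuit state as the relaxation starting
    point; their phenotype follows branch persistence or the saddle-node
    fall-off (``oracle=True`` integrates the ODEs instead of using the
    table's cached outcomes).
    """
    if parent.inputs is not None:
        d1, d2 = partition_inputs(parent.inputs, noise, rng)
        from .circuit import snail_drive

        fates = []
        for vals in (d1, d2):
            drv = snail_drive(0.0, table.params, vals)
            fates.append((drv, table.transition(parent.branch, drv), vals))
        c1 = Cell(parent.id + 1, float(fates[0][0]), fates[0][1], time, parent.id, fates[0][2])
        c2 = Cell(parent.id + 2, float(fates[1][0]), fates[1][1], time, parent.id, fates[1][2])
        return c1, c2
    fates = _daughter_fates(parent.branch, parent.isig, noise, table, rng, oracle)
    (x1, b1), (x2, b2) = fates
    return (
        Cell(parent.id + 1, x1, b1, time, parent.id),
        Cell(parent.id + 2, x2, b2, time, parent.id),
    )


# ---------------------------------------------------------------------------
# Gillespie simulation


def simulate(pop: Population, duration: float, protocol=None,
             sample_interval: float = 24.0,
             rng: np.random.Generator | None = None,
             record_divisions: bool = True) -> tuple[Trajectory, list[DivisionRecord]]:
    """Exact stochastic simulation of the population for ``duration`` hours.

    Division propensity ``b_phi (1 - N/K)`` (floored at zero), death
    propensity ``d_phi`` times any active drug multiplier.  Protocol hooks
    (signal dosing, drug windows) fire at their scheduled times between
    reaction events.  The state is sampled every ``sample_interval`` hours;
    an extinct population terminates early with the trajectory flagged.
    """
    rng = np.random.default_rng() if rng is None else rng
    table, rates, noise = pop.table, pop.rates, pop.noise
    t0 = pop.clock
    t_end = t0 + duration
    K = rates.carrying_capacity
    b = {k: rates.division_rate(k) for k in PHENOTYPES}
    d0 = {k: rates.death(k) for k in PHENOTYPES}

    events = []  # (time, callable) protocol hooks
    if protocol is not None:
        events = sorted(protocol.hooks(pop, t0), key=lambda e: e[0])
    ev_i = 0

    def death_rates(t):
        if protocol is None:
            return d0
        mult = protocol.death_multipliers(t - t0)
        return {k: d0[k] * mult.get(k, 1.0) for k in PHENOTYPES}

    d = death_rates(t0)

    samples_t: list[float] = []
    samples_n: list[tuple[int, int, int]] = []
    samples_div: list[int] = []
    samples_die: list[int] = []
    n_div = n_die = 0
    records: list[DivisionRecord] = []

    def take_sample(ts):
        samples_t.append(ts)
        c = pop.counts()
        samples_n.append((c["E"], c["H"], c["M"]))
        samples_div.append(n_div)
        samples_die.append(n_die)

    take_sample(t0)
    next_sample = t0 + sample_interval

    t = t0
    extinct = False
    isig = pop._isig
    mir34_on = noise.mir34_mode != "off"
    # warm the lazy miR-34a maps outside the hot loop
    if mir34_on:
        table.mir34_outcome("depleted", table.branches["H"].lo)
        if noise.mir34_mode == "zero-double":
            table.mir34_outcome("doubled", table.branches["H"].lo)

    while True:
        nE, nH, nM = len(isig["E"]), len(isig["H"]), len(isig["M"])
        N = nE + nH + nM
        if N == 0:
            extinct = True
            break
        crowd = max(0.0, 1.0 - N / K)
        aE, aH, aM = nE * b["E"] * crowd, nH * b["H"] * crowd, nM * b["M"] * crowd
        eE, eH, eM = nE * d["E"], nH * d["H"], nM * d["M"]
        a0 = aE + aH + aM + eE + eH + eM
        t_next = t + rng.exponential(1.0 / a0) if a0 > 0 else math.inf

        boundary = min(next_sample, t_end,
                       events[ev_i][0] if ev_i < len(events) else math.inf)
        if t_next >= boundary:
            t = boundary
            if ev_i < len(events) and boundary >= events[ev_i][0]:
                events[ev_i][1]()
                ev_i += 1
                d = death_rates(t)
                continue
            if boundary >= t_end:
                if not samples_t or samples_t[-1] < t_end:
                    take_sample(t_end)
                break
            take_sample(boundary)
            next_sample += sample_interval
            continue

        t = t_next
        r = rng.random() * a0
        if r < aE:
            br, idx = "E", int(r / (b["E"] * crowd))
            kind = "div"
        elif r < aE + aH:
            br, idx = "H", int((r - aE) / (b["H"] * crowd))
            kind = "div"
        elif r < aE + aH + aM:
            br, idx = "M", int((r - aE - aH) / (b["M"] * crowd))
            kind = "div"
        elif r < aE + aH + aM + eE:
            br, idx = "E", int((r - aE - aH - aM) / d["E"])
            kind = "die"
        elif r < aE + aH + aM + eE + eH:
            br, idx = "H", int((r - aE - aH - aM - eE) / d["H"])
            kind = "die"
        else:
            br, idx = "M", int((r - aE - aH - aM - eE - eH) / d["M"])
            kind = "die"
        idx = min(idx, len(isig[br]) - 1)

        popped = pop._pop_cell(br, idx)
        if kind == "die":
            n_die += 1
            continue
        n_div += 1
        parent_isig, parent_id = popped[0], popped[1]
        parent_inputs = popped[4] if pop.multi_input else None
        if parent_inputs is not None:
            d1v, d2v = partition_inputs(parent_inputs, noise, rng)
            from .circuit import snail_drive

            fates = []
            for vals in (d1v, d2v):
                drv = snail_drive(0.0, table.params, vals)
                fates.append((drv, table.transition(br, drv), vals))
            for x, nb, vals in fates:
                pop.add_cell(nb, x, t, parent_id, vals)
        else:
            fates = _daughter_fates(br, parent_isig, noise, table, rng)
            for x, nb in fates:
                pop.add_cell(nb, x, t, parent_id)
        if record_divisions:
            records.append(DivisionRecord(t, br, fates[0][1], fates[1][1]))

    pop.clock = t
    counts = {
        k: np.array([s["EHM".index(k)] for s in samples_n])
        for k in PHENOTYPES
    }
    traj = Trajectory(
        np.asarray(samples_t) - t0, counts,
        np.asarray(samples_div), np.asarray(samples_die), extinct,
    )
    return traj, records


def tally_divisions(records: list[DivisionRecord]) -> pd.DataFrame:
    """Division-outcome statistics per parent phenotype.

    Returns, for each parent phenotype present: the average number of
    daughters of each phenotype per division, the probability that at
    least one daughter differs from the parent, and the division count.
    """
    if not records:
        raise ValueError("empty division record list")
    rows = {}
    for parent in PHENOTYPES:
        sub = [r for r in records if r.parent == parent]
        if not sub:
            continue
        n = len(sub)
        avg = {
            f"avg_{k}": sum((r.daughter1 == k) + (r.daughter2 == k) for r in sub) / n
            for k in PHENOTYPES
        }
        p_switch = sum(
            (r.daughter1 != parent) or (r.daughter2 != parent) for r in sub
        ) / n
        rows[parent] = {**avg, "p_any_switch": p_switch, "n_divisions": n}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("parent")
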