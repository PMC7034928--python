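"""Bifurcation structure of the EMP circuit over the EMT-inducing signal.

Builds a :class:`BranchTable`: the existence interval and steady states of
every stable branch family (E, hybrid E/M, M) over a grid of ``Isig``
values, with saddle-node positions refined by bisection, data-derived
ZEB-mRNA classification cutoffs, and precomputed "fall-off" maps recording
which attractor a cell reaches when its branch ceases to exist at the new
signal level.  The fall-off maps let population simulations replace
per-division ODE relaxation by an O(log n) lookup.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import (
    I_MIR34,
    I_ZEB,
    I_ZEB_MRNA,
    PhenotypeThresholds,
    classify_phenotype,
    find_stable_states,
    relax_to_steady_state,
    _polish,
)
from .params import CircuitParams

__all__ = ["Branch", "BranchTable", "scan_bifurcation", "branch_transition", "default_grid"]

# relative log-scale distance on (ZEB mRNA, ZEB protein) used to match
# states to branch families across adjacent grid points
_MATCH_TOL = 0.6


def _state_dist(a: np.ndarray, b: np.ndarray) -> float:
    da = abs(np.log1p(a[I_ZEB_MRNA]) - np.log1p(b[I_ZEB_MRNA]))
    db = abs(np.log1p(a[I_ZEB]) - np.log1p(b[I_ZEB]))
    return max(da, db)


@dataclass
class Branch:
    """One stable branch family: existence interval and states on a grid."""

    label: str  # phenotype, assigned after threshold derivation
    grid: np.ndarray  # axis values where the branch exists (sorted)
    states: np.ndarray  # (len(grid), n_species)
    lo: float  # lower saddle-node (or domain edge)
    hi: float  # upper saddle-node; np.inf if unbounded on the axis

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def state_at(self, x: float) -> np.ndarray:
        """Steady state at ``x`` by linear interpolation (clamped)."""
        g = self.grid
        if x <= g[0]:
            return self.states[0].copy()
        if x >= g[-1]:
            return self.states[-1].copy()
        j = int(np.searchsorted(g, x))
        w = (x - g[j - 1]) / (g[j] - g[j - 1])
        return (1.0 - w) * self.states[j - 1] + w * self.states[j]

    @property
    def mz_range(self) -> tuple[float, float]:
        mz = self.states[:, I_ZEB_MRNA]
        return float(mz.min()), float(mz.max())


@dataclass
class BranchTable:
    """Stable-branch structure of one circuit over the signal axis.

    ``axis`` is ``"isig"`` (molecules/cell) for the standard single-input
    circuit or ``"drive"`` (SNAIL-mRNA production fold-change) for the
    multi-input mode.  ``falloffs`` maps ``(branch label, side)`` — side
    ``"below"``/``"above"`` — to a piecewise-constant outcome function
    ``(breakpoints, labels)``: the attractor reached by relaxation from the
    vanished branch's endpoint state.
    """

    params: CircuitParams
    axis: str
    grid: np.ndarray
    branches: dict[str, Branch]
    thresholds: PhenotypeThresholds
    falloffs: dict[tuple[str, str], tuple[list[float], list[str]]]
    _mir34_maps: dict = field(default_factory=dict, repr=False)

    def branch(self, label: str) -> Branch:
        return self.branches[label]

    def labels_at(self, x: float) -> list[str]:
        """Labels of all branches that exist at ``x``."""
        return [lb for lb, br in self.branches.items() if br.contains(x)]

    def n_stable(self, x: float) -> int:
        return len(self.labels_at(x))

    @property
    def hybrid_width(self) -> float:
        br = self.branches.get("H")
        return 0.0 if br is None else br.hi - br.lo

    @property
    def saddle_nodes(self) -> dict[str, tuple[float, float]]:
        return {lb: (br.lo, br.hi) for lb, br in self.branches.items()}

    def transition(self, parent_label: str, x: float) -> str:
        """Branch of a daughter cell: see :func:`branch_transition`."""
        if not np.isfinite(x) or x < 0:
            raise ValueError(f"signal level {x} outside table range")
        br = self.branches[parent_label]
        if br.lo <= x <= br.hi:
            return parent_label
        side = "below" if x < br.lo else "above"
        try:
            breaks, labels = self.falloffs[(parent_label, side)]
        except KeyError:
            raise ValueError(
                f"signal level {x} outside table range for branch {parent_label}"
            ) from None
        return labels[bisect.bisect_right(breaks, x)]

    def state_of(self, label: str, x: float) -> np.ndarray:
        return self.branches[label].state_at(x)

    def classify(self, state) -> str:
        return classify_phenotype(state, self.thresholds)

    # -- asymmetric miR-34a division outcomes ---------------------------

    def mir34_outcome(self, kind: str, x: float) -> str:
        """Attractor reached by a hybrid daughter with perturbed miR-34a.

        ``kind`` is ``"depleted"`` (miR-34a set to 0) or ``"doubled"``
        (2x the parent concentration).  Outcomes are relaxed once per grid
        point of the hybrid branch and cached.
        """
        if kind not in ("depleted", "doubled"):
            raise ValueError(f"unknown miR-34a perturbation {kind!r}")
        if kind not in self._mir34_maps:
            self._mir34_maps[kind] = self._build_mir34_map(kind)
        grid, labels = self._mir34_maps[kind]
        j = int(np.clip(np.searchsorted(grid, x), 0, len(labels) - 1))
        return labels[j]

    def _build_mir34_map(self, kind: str):
        br = self.branches["H"]
        labels = []
        for x, state in zip(br.grid, br.states):
            y = state.copy()
            y[I_MIR34] = 0.0 if kind == "depleted" else 2.0 * y[I_MIR34]
            drive = x if self.axis == "drive" else None
            final = relax_to_steady_state(
                y, x if self.axis == "isig" else 0.0, self.params, drive=drive
            )
            labels.append(self._nearest_label(final, x))
        return br.grid.copy(), labels

    def _nearest_label(self, state: np.ndarray, x: float) -> str:
        cands = [
            (lb, _state_dist(state, self.branches[lb].state_at(x)))
            for lb in self.labels_at(x)
        ]
        if not cands:
            raise RuntimeError(f"no branch exists at {x}")
        return min(cands, key=lambda t: t[1])[0]

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (axis value, branch)."""
        rows = []
        species = self.params.species
        for lb, br in self.branches.items():
            for x, st in zip(br.grid, br.states):
                row = {self.axis: x, "branch": lb}
                row.update({s: v for s, v in zip(species, st)})
                rows.append(row)
        return pd.DataFrame(rows).sort_values([self.axis, "branch"]).reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_grid(p: CircuitParams) -> np.ndarray:
    """Axis grid covering beyond both outermost saddle-nodes."""
    if p.variant == "core":
        return np.arange(0.0, 120001.0, 2000.0)
    return np.arange(0.0, 300001.0, 2500.0)


def _exists_at(p: CircuitParams, axis: str, x: float, seed: np.ndarray) -> np.ndarray | None:
    drive = x if axis == "drive" else None
    isig = x if axis == "isig" else 0.0
    y = _polish(seed, isig, p, drive)
    if y is None or _state_dist(y, seed) > _MATCH_TOL:
        return None
    return y


def _bisect_saddle(p, axis, x_in, x_out, seed, rtol=1e-6):
    """Refine a branch endpoint between the last existing and first missing point."""
    y = seed
    scale = max(abs(x_in), abs(x_out), 1.0)
    while abs(x_out - x_in) > rtol * scale:
        mid = 0.5 * (x_in + x_out)
        ym = _exists_at(p, axis, mid, y)
        if ym is not None:
            x_in, y = mid, ym
        else:
            x_out = mid
    return 0.5 * (x_in + x_out), y


def scan_bifurcation(p: CircuitParams, grid: np.ndarray | None = None,
                     axis: str = "isig", refine: bool = True,
                     falloff_step: float | None = None,
                     reference_thresholds: PhenotypeThresholds | None = None) -> BranchTable:
    """Map the stable-branch structure over the signal axis.

    Marches the grid with continuation (states found at the previous point
    seed the root search at the next), stitches states into branch families
    by nearest-state matching, refines each saddle-node by bisection on
    branch existence (relative precision 1e-4) and precomputes relaxation
    fall-off maps at each saddle.

    The untreated circuits have three families (E < H < M in ZEB mRNA) and
    derive their classification cutoffs from the gaps between branch mz
    ranges.  Strongly treated circuits (e.g. saturating retinoic acid) can
    lose branches; then ``reference_thresholds`` (typically from the
    untreated table) must be supplied to label the remaining families.

    Raises
    ------
    RuntimeError
        On ambiguous branch matching, or if the stitched families cannot
        be labelled consistently.
    """
    if grid is None:
        grid = default_grid(p)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be sorted, non-negative")

    families: list[dict] = []  # {'grid': [x...], 'states': [y...], 'open': bool}

    for x in grid:
        drive = x if axis == "drive" else None
        isig = x if axis == "isig" else 0.0
        seeds = [f["states"][-1] for f in families if f["open"]]
        states = [y for y, _ in find_stable_states(
            isig, p, seeds=seeds, relax_seeds=False, drive=drive)]
        active = [f for f in families if f["open"]]
        assigned: dict[int, tuple[int, float]] = {}
        unmatched = []
        for y in states:
            dists = [(i, _state_dist(y, f["states"][-1])) for i, f in enumerate(active)]
            dists = [t for t in dists if t[1] < _MATCH_TOL]
            if not dists:
                unmatched.append(y)
                continue
            i, d = min(dists, key=lambda t: t[1])
            if i in assigned:
                raise RuntimeError(
                    f"ambiguous branch matching at {axis}={x}: two states map "
                    f"to one family (distances {assigned[i][1]:.3f}, {d:.3f})"
                )
            assigned[i] = (len(unmatched), d)
            active[i]["grid"].append(x)
            active[i]["states"].append(y)
        for i, f in enumerate(active):
            if i not in assigned:
                f["open"] = False
        for y in unmatched:
            families.append({"grid": [x], "states": [y], "open": True})

    families = _merge_gap_families(families, grid)
    if not 1 <= len(families) <= 3:
        raise RuntimeError(
            f"stitched {len(families)} stable branch families; "
            "refine the grid or check parameters"
        )
    # order families E < H < M by median ZEB mRNA
    families.sort(key=lambda f: float(np.median([s[I_ZEB_MRNA] for s in f["states"]])))
    if len(families) == 3:
        labels = ["E", "H", "M"]
    else:
        if reference_thresholds is None:
            raise RuntimeError(
                f"only {len(families)} branch families found; supply "
                "reference_thresholds (e.g. from the untreated circuit) to "
                "label them"
            )
        labels = [
            classify_phenotype(
                float(np.median([s[I_ZEB_MRNA] for s in f["states"]])),
                reference_thresholds,
            )
            for f in families
        ]
        if len(set(labels)) != len(labels):
            raise RuntimeError(f"families labelled ambiguously: {labels}")

    branches: dict[str, Branch] = {}
    for lb, f in zip(labels, families):
        g = np.asarray(f["grid"])
        st = np.asarray(f["states"])
        # the march can miss a branch at isolated grid points (multi-start
        # failure); extend each family outward by continuation before
        # treating the first missing grid point as a saddle
        j = int(np.searchsorted(grid, g[0])) - 1
        while j >= 0:
            y = _exists_at(p, axis, grid[j], st[0])
            if y is None:
                break
            g = np.insert(g, 0, grid[j]); st = np.vstack([y, st]); j -= 1
        j = int(np.searchsorted(grid, g[-1])) + 1
        while j < len(grid):
            y = _exists_at(p, axis, grid[j], st[-1])
            if y is None:
                break
            g = np.append(g, grid[j]); st = np.vstack([st, y]); j += 1
        lo, hi = g[0], g[-1]
        lo_seed, hi_seed = st[0], st[-1]
        if refine:
            if lo > grid[0]:
                j = int(np.searchsorted(grid, lo))
                lo, lo_seed = _bisect_saddle(p, axis, lo, grid[j - 1], st[0])
            if hi < grid[-1]:
                j = int(np.searchsorted(grid, hi))
                hi, hi_seed = _bisect_saddle(p, axis, hi, grid[j + 1], st[-1])
        if hi >= grid[-1]:
            hi = np.inf
        if lo <= grid[0]:
            lo = grid[0]
        # extend tabulated states to the refined endpoints
        if lo < g[0] and lo > grid[0]:
            g = np.insert(g, 0, lo); st = np.vstack([lo_seed, st])
        if np.isfinite(hi) and hi > g[-1]:
            g = np.append(g, hi); st = np.vstack([st, hi_seed])
        branches[lb] = Branch(lb, g, st, float(lo), float(hi))

    if len(branches) == 3:
        thresholds = _derive_thresholds(branches)
    else:
        thresholds = reference_thresholds
    table = BranchTable(p, axis, grid, branches, thresholds, {})
    table.falloffs.update(_build_falloffs(table, falloff_step))
    return table


def _merge_gap_families(families: list[dict], grid: np.ndarray) -> list[dict]:
    """Repair single-point dropouts that split one branch into two families."""
    families = sorted(families, key=lambda f: f["grid"][0])
    merged: list[dict] = []
    for f in families:
        if merged:
            prev = merged[-1]
            gap = f["grid"][0] - prev["grid"][-1]
            step = float(np.max(np.diff(grid))) if len(grid) > 1 else np.inf
            if (
                gap <= 2.001 * step
                and _state_dist(np.asarray(f["states"][0]), np.asarray(prev["states"][-1]))
                < 2 * _MATCH_TOL
            ):
                prev["grid"].extend(f["grid"])
                prev["states"].extend(f["states"])
                prev["open"] = f["open"]
                continue
        merged.append(f)
    return merged


def _derive_thresholds(branches: dict[str, Branch]) -> PhenotypeThresholds:
    """ZEB-mRNA cutoffs: midpoints between adjacent branch mz ranges."""
    e_hi = branches["E"].mz_range[1]
    h_lo, h_hi = branches["H"].mz_range
    m_lo = branches["M"].mz_range[0]
    if not (e_hi < h_lo and h_hi < m_lo):
        raise RuntimeError(
            f"branch ZEB-mRNA ranges overlap (E<= {e_hi:.0f}, H [{h_lo:.0f},"
            f" {h_hi:.0f}], M >= {m_lo:.0f}); cannot derive cutoffs"
        )
    return PhenotypeThresholds(0.5 * (e_hi + h_lo), 0.5 * (h_hi + m_lo))


def _build_falloffs(table: BranchTable, step: float | None):
    """Relaxation outcomes beyond each saddle, as piecewise-constant maps.

    Samples the axis beyond the saddle at ``step`` resolution, relaxes the
    branch's endpoint state at each sample, and bisects outcome boundaries
    to ~``step/16``.
    """
    p = table.params
    grid = table.grid
    if step is None:
        step = 2.0 * float(np.max(np.diff(grid)))
    out: dict[tuple[str, str], tuple[list[float], list[str]]] = {}

    def relax_label(endpoint_state: np.ndarray, x: float) -> str:
        drive = x if table.axis == "drive" else None
        isig = x if table.axis == "isig" else 0.0
        final = relax_to_steady_state(endpoint_state, isig, p, drive=drive)
        return table._nearest_label(final, x)

    for lb, br in table.branches.items():
        for side in ("below", "above"):
            if side == "below":
                if br.lo <= grid[0]:
                    continue
                xs = list(np.arange(br.lo - 1e-3 * step, grid[0], -step)) + [grid[0]]
                endpoint = br.states[0]
            else:
                if not np.isfinite(br.hi) or br.hi >= grid[-1]:
                    continue
                xs = list(np.arange(br.hi + 1e-3 * step, grid[-1], step)) + [grid[-1]]
                endpoint = br.states[-1]
            labels = [relax_label(endpoint, x) for x in xs]
            # bisect outcome boundaries between samples with different labels
            breaks: list[float] = []
            kept: list[str] = [labels[0]]
            for (x0, l0), (x1, l1) in zip(zip(xs, labels), zip(xs[1:], labels[1:])):
                if l1 == kept[-1]:
                    continue
                a, b = x0, x1
                for _ in range(8):
                    mid = 0.5 * (a + b)
                    if relax_label(endpoint, mid) == l0:
                        a = mid
                    else:
                        b = mid
                cut = 0.5 * (a + b)
                # an outcome boundary that coincides with another branch's
                # saddle must match it exactly, or interval membership and
                # fall-off lookups disagree within the bisection resolution
                for other in table.branches.values():
                    for saddle in (other.lo, other.hi):
                        if np.isfinite(saddle) and abs(saddle - cut) < abs(x1 - x0):
                            cut = saddle
                breaks.append(cut)
                kept.append(l1)
            if side == "below":
                # xs descend; re-sort to ascending for bisect queries
                breaks = breaks[::-1]
                kept = kept[::-1]
            out[(lb, side)] = (breaks, kept)
    return out


def branch_transition(parent_label: str, daughter_x: float, table: BranchTable) -> str:
    """Branch/phenotype a daughter settles on at its new signal level.

    If the parent's branch still exists there, the daughter stays on it;
    otherwise the precomputed relaxation fall-off for that saddle decides.
    """
    return table.transition(parent_label, daughter_x)
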