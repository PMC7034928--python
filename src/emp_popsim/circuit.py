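"""Deterministic dynamics of the EMP regulatory circuit.

Right-hand side, steady states, stability, relaxation and phenotype
classification for the miR-34/SNAIL -- miR-200/ZEB ternary switch and its
stabilizer variants.  The bifurcation parameter is the lumped EMT-inducing
signal ``Isig`` (molecules/cell) activating SNAIL transcription.

Phenotypes are assigned from ZEB mRNA copy number: epithelial below the
lower cutoff, mesenchymal above the upper one, hybrid E/M in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import CircuitParams, MicroRNABindings

__all__ = [
    "shifted_hill",
    "mirna_factors",
    "snail_drive",
    "circuit_rhs",
    "circuit_jacobian",
    "PhenotypeThresholds",
    "classify_phenotype",
    "relax_to_steady_state",
    "find_stable_states",
    "is_stable_state",
    "archetype_states",
]

PHENOTYPES = ("E", "H", "M")

# index constants into the state vector
I_MIR200, I_ZEB_MRNA, I_ZEB, I_MIR34, I_SNAIL_MRNA, I_SNAIL = range(6)
I_X = 6


def shifted_hill(X, X0: float, n: int, lam: float):
    """Shifted Hill fold-change ``(1 + lam (X/X0)^n) / (1 + (X/X0)^n)``.

    Equals 1 at ``X = 0`` and saturates at ``lam``; ``lam > 1`` activates,
    ``lam < 1`` represses.  Accepts scalars or arrays.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite regulator concentration")
    if np.any(X < 0):
        raise ValueError("negative regulator concentration")
    if X0 <= 0 or n < 1 or lam <= 0:
        raise ValueError("require X0 > 0, n >= 1, lam > 0")
    r = (X / X0) ** n
    out = (1.0 + lam * r) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def _hill(X: float, link) -> float:
    # scalar fast path used by the RHS (no validation overhead)
    r = (X / link.X0) ** link.n
    return (1.0 + link.lam * r) / (1.0 + r)


def mirna_factors(u: float, b: MicroRNABindings) -> tuple[float, float, float]:
    """Translation factor L, mRNA degradation Ym and microRNA degradation Yu.

    Binomially weighted over the number of microRNAs bound to the mRNA; see
    :class:`~emp_popsim.params.MicroRNABindings`.
    """
    n = b.n_sites
    mu = u / b.u0
    den = (1.0 + mu) ** n
    L = Ym = Yu = 0.0
    w = 1.0
    for i in range(n + 1):
        binom = math.comb(n, i)
        L += b.l[i] * binom * w
        Ym += b.gm[i] * binom * w
        Yu += b.gu[i] * i * binom * w
        w *= mu
    return L / den, Ym / den, Yu / den


def snail_drive(isig: float, p: CircuitParams,
                input_values: "np.ndarray | None" = None) -> float:
    """Production fold-change on SNAIL mRNA from the external signal(s).

    Single-input mode: one shifted-Hill factor in ``Isig``.  Multi-input
    mode (``p.inputs`` non-empty): the product of one factor per input, all
    sharing the core threshold and Hill coefficient, with fold-change 10
    for activating and 0.1 for inhibiting inputs.  Any exogenous treatment
    factor (RA / TGF-beta) multiplies on top.
    """
    link = p.isig_on_snail_mrna
    if p.inputs:
        if input_values is None:
            raise ValueError("multi-input parameter set requires input values")
        vals = np.asarray(input_values, dtype=float)
        if len(vals) != len(p.inputs):
            raise ValueError(
                f"{len(vals)} input values for {len(p.inputs)} declared inputs"
            )
        drive = 1.0
        for spec, v in zip(p.inputs, vals):
            r = (v / link.X0) ** link.n
            drive *= (1.0 + spec.fold_change() * r) / (1.0 + r)
    else:
        drive = _hill(isig, link)
    return drive * p.snail_mrna_production_factor


def circuit_rhs(state, isig: float, p: CircuitParams,
                drive: float | None = None) -> np.ndarray:
    """Time derivatives (molecules/h) of every circuit species.

    ``drive`` overrides the external SNAIL-mRNA production fold-change
    (used by the multi-input mode and drive-axis bifurcation scans);
    otherwise it is computed from ``isig``.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (p.n_species,):
        raise ValueError(
            f"state has {y.shape} entries; variant '{p.variant}' needs {p.n_species}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite circuit state")
    y = np.maximum(y, 0.0)
    u200, mz, Z, u34, ms, S = y[:6]
    if drive is None:
        drive = snail_drive(isig, p)

    L200, Ym200, Yu200 = mirna_factors(u200, p.mir200_zeb)
    L34, Ym34, Yu34 = mirna_factors(u34, p.mir34_snail)

    mz_production = (
        p.g_zeb_mrna
        * _hill(Z, p.zeb_on_zeb_mrna)
        * _hill(S, p.snail_on_zeb_mrna)
    )
    out = np.empty(p.n_species)
    if p.variant != "core":
        X = y[I_X]
        st = p.stabilizer
        mz_production *= _hill(X, st.x_on_zeb_mrna)
        out[I_X] = st.g * _hill(Z, st.zeb_on_x) - st.k * X

    out[I_MIR200] = (
        p.g_mir200 * _hill(Z, p.zeb_on_mir200) * _hill(S, p.snail_on_mir200)
        - mz * Yu200
        - p.k_mir200 * u200
    )
    out[I_ZEB_MRNA] = mz_production - mz * Ym200 - p.k_zeb_mrna * mz
    out[I_ZEB] = p.g_zeb * mz * L200 - p.k_zeb * Z
    out[I_MIR34] = (
        p.g_mir34 * _hill(S, p.snail_on_mir34) * _hill(Z, p.zeb_on_mir34)
        - ms * Yu34
        - p.k_mir34 * u34
    )
    out[I_SNAIL_MRNA] = (
        p.g_snail_mrna * drive * _hill(S, p.snail_on_snail_mrna)
        - ms * Ym34
        - p.k_snail_mrna * ms
    )
    out[I_SNAIL] = p.g_snail * ms * L34 - p.k_snail * S
    return out


def circuit_jacobian(state, isig: float, p: CircuitParams,
                     drive: float | None = None) -> np.ndarray:
    """Jacobian of :func:`circuit_rhs`, by central finite differences."""
    y = np.maximum(np.asarray(state, dtype=float), 0.0)
    n = p.n_species
    J = np.empty((n, n))
    for j in range(n):
        h = max(1e-6 * abs(y[j]), 1e-4)
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] = max(ym[j] - h, 0.0)
        J[:, j] = (circuit_rhs(yp, isig, p, drive) - circuit_rhs(ym, isig, p, drive)) / (
            yp[j] - ym[j]
        )
    return J


@dataclass(frozen=True)
class PhenotypeThresholds:
    """ZEB-mRNA cutoffs separating E | hybrid E/M | M."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("require 0 < lower < upper")


def classify_phenotype(state, thresholds: PhenotypeThresholds) -> str:
    """Phenotype from ZEB mRNA level: E below, M above, H between."""
    mz = float(np.asarray(state, dtype=float)[I_ZEB_MRNA]) if np.ndim(state) else float(state)
    if mz < thresholds.lower:
        return "E"
    if mz > thresholds.upper:
        return "M"
    return "H"


def _residual_scale(y: np.ndarray, f: np.ndarray) -> float:
    return float(np.max(np.abs(f) / (1.0 + np.abs(y))))


def relax_to_steady_state(init, isig: float, p: CircuitParams,
                          tol: float = 1e-6, chunk: float = 400.0,
                          max_time: float = 40000.0,
                          drive: float | None = None) -> np.ndarray:
    """Integrate the circuit ODEs at fixed signal until a stable state.

    Integrates in chunks of ``chunk`` hours until the scaled residual
    ``max_i |dy_i/dt| / (1 + |y_i|)`` drops below ``tol``.  This is the
    daughter-cell relaxation rule: after division the inherited circuit
    state settles onto an attractor at the (possibly new) signal level.

    Raises
    ------
    RuntimeError
        If no steady state is attained within ``max_time`` hours.
    """
    y = np.maximum(np.asarray(init, dtype=float), 0.0)
    if y.shape != (p.n_species,):
        raise ValueError("initial state has wrong dimension for this variant")
    t = 0.0
    while t < max_time:
        sol = solve_ivp(
            lambda _t, yy: circuit_rhs(yy, isig, p, drive),
            (0.0, chunk), y, method="LSODA", rtol=1e-8, atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed at Isig={isig}: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        t += chunk
        if _residual_scale(y, circuit_rhs(y, isig, p, drive)) < tol:
            return y
    raise RuntimeError(
        f"no steady state within {max_time} h at Isig={isig} (residual "
        f"{_residual_scale(y, circuit_rhs(y, isig, p, drive)):.2e})"
    )


def archetype_states(p: CircuitParams) -> list[np.ndarray]:
    """Deterministic initial guesses spanning the three attractor families."""
    guesses = [
        [20000.0, 20.0, 1000.0, 10000.0, 500.0, 100000.0],  # E-like
        [9000.0, 400.0, 90000.0, 14000.0, 800.0, 250000.0],  # hybrid-like
        [800.0, 1000.0, 800000.0, 8000.0, 1500.0, 400000.0],  # M-like
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # origin (pure production)
    ]
    out = []
    for g in guesses:
        y = np.array(g, dtype=float)
        if p.variant != "core":
            st = p.stabilizer
            x = st.g / st.k * _hill(y[I_ZEB], st.zeb_on_x)
            y = np.append(y, x)
        out.append(y)
    return out


def is_stable_state(state, isig: float, p: CircuitParams,
                    tol: float = 1e-6, drive: float | None = None) -> bool:
    """True if ``state`` is a fixed point with a strictly stable Jacobian."""
    y = np.asarray(state, dtype=float)
    if _residual_scale(y, circuit_rhs(y, isig, p, drive)) > tol:
        return False
    eig = np.linalg.eigvals(circuit_jacobian(y, isig, p, drive))
    return bool(np.max(eig.real) < 0.0)


def _polish(seed: np.ndarray, isig: float, p: CircuitParams,
            drive: float | None) -> np.ndarray | None:
    sol = root(lambda y: circuit_rhs(y, isig, p, drive), seed, method="hybr",
               options={"xtol": 1e-12})
    if not sol.success:
        return None
    y = sol.x
    if np.any(y < -1e-3 * np.maximum(1.0, np.abs(y))):
        return None
    y = np.maximum(y, 0.0)
    if not is_stable_state(y, isig, p, drive=drive):
        return None
    return y


def _dedupe(states: list[np.ndarray], rtol: float = 1e-6) -> list[np.ndarray]:
    uniq: list[np.ndarray] = []
    for y in states:
        if not any(
            np.allclose(y, u, rtol=max(rtol, 1e-6), atol=1.0) for u in uniq
        ):
            uniq.append(y)
    return uniq


def find_stable_states(isig: float, p: CircuitParams,
                       thresholds: PhenotypeThresholds | None = None,
                       seeds: list[np.ndarray] | None = None,
                       relax_seeds: bool = True,
                       drive: float | None = None) -> list[tuple[np.ndarray, str | None]]:
    """All stable fixed points at one signal level, with phenotype labels.

    Multi-start root finding from a deterministic set of initial guesses
    (archetypes spanning the three attractor families, plus any caller-
    provided continuation seeds), each optionally pre-relaxed by a short
    ODE integration so the Newton polish starts inside a basin.  States are
    deduplicated at relative tolerance 1e-6 and checked for linear
    stability.  If ``thresholds`` is None, labels are None (the bifurcation
    scan assigns phenotypes after deriving data-driven cutoffs).

    Raises
    ------
    RuntimeError
        If not a single stable state converged (bad parameters).
    """
    all_seeds = [] if seeds is None else [np.asarray(s, dtype=float) for s in seeds]
    found: list[np.ndarray] = []
    for s in all_seeds:
        y = _polish(s, isig, p, drive)
        if y is not None:
            found.append(y)
    for s in archetype_states(p):
        if relax_seeds:
            sol = solve_ivp(lambda _t, yy: circuit_rhs(yy, isig, p, drive),
                            (0.0, 150.0), s, method="LSODA", rtol=1e-6, atol=1e-6)
            if sol.success:
                s = np.maximum(sol.y[:, -1], 0.0)
        y = _polish(s, isig, p, drive)
        if y is not None:
            found.append(y)
    if not found and not relax_seeds:
        # retry with relaxed archetypes: slower but basin-robust
        return find_stable_states(isig, p, thresholds, seeds, True, drive)
    uniq = _dedupe(found)
    if not uniq:
        raise RuntimeError(f"no stable state found at Isig={isig}")
    uniq.sort(key=lambda y: y[I_ZEB_MRNA])
    if thresholds is None:
        return [(y, None) for y in uniq]
    return [(y, classify_phenotype(y, thresholds)) for y in uniq]
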