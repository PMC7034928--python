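"""Division-time partitioning noise models.

At cell division the parent's biomolecules are apportioned between the two
daughters.  The dominant perturbation is carried by the lumped EMT-inducing
signal ``Isig``: a daughter's level is the parent's plus additive Gaussian
noise of standard deviation ``eta`` (molecules/cell), truncated at zero.
Optional extras: multiplicative partitioning noise on every circuit species
(coefficient of variation ``cv_species``), asymmetric miR-34a partitioning
during hybrid E/M divisions (the stem-like division mode), and independent
per-input noise in the multi-input variant.

Two conventions relate the daughters to the parent (see docs/methods.md):

* ``"birth"`` (default) — a division is a Gillespie birth event: one
  daughter continues with the parent's signal level, the newborn receives
  the noisy partition.
* ``"symmetric"`` — both daughters receive independent noisy partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "NoiseSpec",
    "partition_isig",
    "partition_mir34a",
    "partition_all_species",
    "partition_inputs",
]

from .circuit import I_MIR34


@dataclass(frozen=True)
class NoiseSpec:
    """Configuration of every division-time noise source.

    Parameters
    ----------
    eta : float
        SD of the additive Isig partitioning noise, molecules/cell.
    cv_species : float
        Coefficient of variation of multiplicative partitioning noise on
        every circuit species (0 disables; 0.25 in the all-species mode).
    mir34_mode : {"off", "zero-one", "zero-double"}
        Asymmetric miR-34a partitioning during hybrid E/M division: one
        daughter gets no miR-34a, the other keeps the parent concentration
        ("zero-one") or twice it ("zero-double").
    etas : tuple of float, optional
        One noise SD per input in multi-input mode.
    convention : {"birth", "symmetric"}
        How daughters relate to the parent (module docstring).
    """

    eta: float = 2.7e4
    cv_species: float = 0.0
    mir34_mode: str = "off"
    etas: tuple[float, ...] = ()
    convention: str = "birth"

    def __post_init__(self) -> None:
        if self.eta < 0 or self.cv_species < 0 or any(e < 0 for e in self.etas):
            raise ValueError("noise magnitudes must be non-negative")
        if self.mir34_mode not in ("off", "zero-one", "zero-double"):
            raise ValueError(f"unknown miR-34a mode {self.mir34_mode!r}")
        if self.convention not in ("birth", "symmetric"):
            raise ValueError(f"unknown partition convention {self.convention!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        d = dict(d)
        if "etas" in d:
            d["etas"] = tuple(d["etas"])
        return cls(**d)


def partition_isig(parent_isig: float, spec: NoiseSpec,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Signal levels of the two daughters after a division.

    Each daughter receives ``parent + eta * N(0, 1)`` with independent
    standard-normal draws, truncated at zero (the signal concentration
    cannot be negative).
    """
    if parent_isig < 0 or not np.isfinite(parent_isig):
        raise ValueError("parent Isig must be finite and non-negative")
    z1, z2 = rng.standard_normal(2)
    return (
        max(0.0, parent_isig + spec.eta * z1),
        max(0.0, parent_isig + spec.eta * z2),
    )


def partition_mir34a(parent_state, parent_phenotype: str, spec: NoiseSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Daughter circuit states under asymmetric miR-34a partitioning.

    Applies only to hybrid E/M parents (the stem-like state with
    intermediate miR-34a): one daughter, chosen by fair coin, gets zero
    miR-34a; the other keeps the parent concentration ("zero-one") or
    twice it ("zero-double").  Epithelial and mesenchymal divisions copy
    the parent state unchanged.
    """
    if spec.mir34_mode == "off":
        raise ValueError("asymmetric miR-34a mode is off")
    s1 = np.asarray(parent_state, dtype=float).copy()
    s2 = s1.copy()
    if parent_phenotype != "H":
        return s1, s2
    factor = 1.0 if spec.mir34_mode == "zero-one" else 2.0
    if rng.random() < 0.5:
        s1[I_MIR34] = 0.0
        s2[I_MIR34] *= factor
    else:
        s2[I_MIR34] = 0.0
        s1[I_MIR34] *= factor
    return s1, s2


def partition_all_species(parent_state, spec: NoiseSpec,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent multiplicative noise on every species of each daughter.

    Each species ``x`` becomes ``x * (1 + cv * N(0, 1))``, truncated at 0.
    """
    if spec.cv_species <= 0:
        raise ValueError("cv_species must be positive for all-species noise")
    s = np.asarray(parent_state, dtype=float)
    d1 = np.maximum(s * (1.0 + spec.cv_species * rng.standard_normal(s.shape)), 0.0)
    d2 = np.maximum(s * (1.0 + spec.cv_species * rng.standard_normal(s.shape)), 0.0)
    return d1, d2


def partition_inputs(parent_inputs, spec: NoiseSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-input Eq-1 partitioning in the multi-input mode.

    Every input of every daughter receives an independent Gaussian
    perturbation with its own noise SD; a single input with
    ``etas == (eta,)`` reduces exactly to :func:`partition_isig`.
    """
    x = np.asarray(parent_inputs, dtype=float)
    if len(spec.etas) != x.size:
        raise ValueError(
            f"{x.size} inputs but {len(spec.etas)} noise SDs declared"
        )
    etas = np.asarray(spec.etas)
    d1 = np.maximum(x + etas * rng.standard_normal(x.shape), 0.0)
    d2 = np.maximum(x + etas * rng.standard_normal(x.shape), 0.0)
    return d1, d2
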