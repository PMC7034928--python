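"""Kinetic parameters of the EMP regulatory circuit and its variants.

The core circuit is the miR-34/SNAIL -- miR-200/ZEB ternary switch: SNAIL,
driven by a lumped EMT-inducing signal ``Isig``, represses miR-200 and
activates ZEB transcription; ZEB and miR-200 mutually inhibit each other
(ZEB mRNA carries six miR-200 binding sites), and miR-34 forms an analogous
mutually-inhibitory module with SNAIL (two binding sites on SNAIL mRNA).
All copy numbers are molecules per cell, all rates per hour.

Two "phenotypic stability factor" variants append a species ``X`` in mutual
inhibition with ZEB (ZEB represses X transcription, X represses ZEB
transcription): GRHL2 and dNP63a.  Their couplings differ only in strength
and widen the Isig range over which the hybrid E/M state exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import yaml

Variant = Literal["core", "grhl2", "dnp63a"]

#: Species names, in state-vector order.  Variant circuits append "x" (the
#: stabilizer protein).
CORE_SPECIES = ("mir200", "zeb_mrna", "zeb", "mir34", "snail_mrna", "snail")


@dataclass(frozen=True)
class HillLink:
    """One shifted-Hill regulatory link.

    ``lam > 1`` activates, ``lam < 1`` inhibits; the fold-change is 1 at zero
    regulator and saturates at ``lam``.
    """

    X0: float
    n: int
    lam: float

    def __post_init__(self) -> None:
        if not (self.X0 > 0 and math.isfinite(self.X0)):
            raise ValueError(f"Hill threshold must be positive, got {self.X0}")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"Hill coefficient must be integer >= 1, got {self.n}")
        if not (self.lam > 0):
            raise ValueError(f"fold-change must be positive, got {self.lam}")


@dataclass(frozen=True)
class MicroRNABindings:
    """Combinatorial microRNA-mRNA interaction weights.

    For an mRNA with ``n`` microRNA binding sites, the translation factor,
    the active-mRNA-degradation rate and the microRNA co-degradation rate are
    binomially weighted sums over the number of bound microRNAs ``i``::

        L(u)  = sum_i l[i]  C(n,i) (u/u0)^i / (1+u/u0)^n
        Ym(u) = sum_i gm[i] C(n,i) (u/u0)^i / (1+u/u0)^n
        Yu(u) = sum_i gu[i] i C(n,i) (u/u0)^i / (1+u/u0)^n

    ``l`` are per-occupancy translation silencing factors, ``gm``/``gu``
    per-occupancy degradation rates (1/h).
    """

    u0: float
    l: tuple[float, ...]
    gm: tuple[float, ...]
    gu: tuple[float, ...]

    @property
    def n_sites(self) -> int:
        return len(self.l) - 1

    def __post_init__(self) -> None:
        if not (len(self.l) == len(self.gm) == len(self.gu)):
            raise ValueError("binding weight vectors must share length n_sites+1")
        if self.u0 <= 0:
            raise ValueError("microRNA binding threshold u0 must be positive")


@dataclass(frozen=True)
class InputSpec:
    """One signal in the multi-input mode of SNAIL regulation.

    Each input multiplies SNAIL-mRNA production by a shifted-Hill factor
    sharing the core Isig threshold and Hill coefficient; only the
    fold-change differs by role (10.0 activating, 0.1 inhibiting).
    """

    role: Literal["activating", "inhibiting"]
    lam: float | None = None

    def fold_change(self) -> float:
        if self.lam is not None:
            return self.lam
        return 10.0 if self.role == "activating" else 0.1


@dataclass(frozen=True)
class StabilizerParams:
    """Mutual-inhibition coupling of a phenotypic stability factor X to ZEB."""

    g: float  # production, molecules/h
    k: float  # degradation, 1/h
    zeb_on_x: HillLink  # ZEB -| X transcription
    x_on_zeb_mrna: HillLink  # X -| ZEB-mRNA transcription

    def __post_init__(self) -> None:
        if self.g <= 0 or self.k <= 0:
            raise ValueError("stabilizer rates must be positive")
        if self.zeb_on_x.lam >= 1 or self.x_on_zeb_mrna.lam >= 1:
            raise ValueError("stabilizer couplings are inhibitory (lam < 1)")


@dataclass(frozen=True)
class CircuitParams:
    """Full kinetic parameterization of the EMP circuit.

    Production rates ``g_*`` (molecules/h), degradation rates ``k_*`` (1/h),
    one :class:`HillLink` per transcriptional link, and the two
    :class:`MicroRNABindings` tables.  ``stabilizer`` is set for the GRHL2 /
    dNP63a variants; ``inputs`` switches SNAIL regulation to multi-input mode.
    """

    # production (molecules / h)
    g_mir200: float = 2100.0
    g_zeb_mrna: float = 11.0
    g_zeb: float = 100.0  # per mRNA per h
    g_mir34: float = 1350.0
    g_snail_mrna: float = 90.0
    g_snail: float = 100.0  # per mRNA per h
    # degradation (1 / h)
    k_mir200: float = 0.05
    k_zeb_mrna: float = 0.5
    k_zeb: float = 0.1
    k_mir34: float = 0.05
    k_snail_mrna: float = 0.5
    k_snail: float = 0.125
    # transcriptional links (shifted Hill)
    zeb_on_mir200: HillLink = HillLink(220000.0, 3, 0.1)
    snail_on_mir200: HillLink = HillLink(180000.0, 2, 0.1)
    zeb_on_zeb_mrna: HillLink = HillLink(25000.0, 2, 7.5)  # self-activation
    snail_on_zeb_mrna: HillLink = HillLink(180000.0, 2, 10.0)
    zeb_on_mir34: HillLink = HillLink(600000.0, 1, 0.2)
    snail_on_mir34: HillLink = HillLink(300000.0, 1, 0.1)
    isig_on_snail_mrna: HillLink = HillLink(50000.0, 2, 10.0)
    snail_on_snail_mrna: HillLink = HillLink(200000.0, 1, 0.1)  # self-inhibition
    # microRNA-mRNA binding tables
    mir200_zeb: MicroRNABindings = MicroRNABindings(
        10000.0,
        (1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
        (0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0),
        (0.0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5),
    )
    mir34_snail: MicroRNABindings = MicroRNABindings(
        10000.0, (1.0, 0.6, 0.3), (0.0, 0.04, 0.2), (0.0, 0.005, 0.05)
    )
    variant: Variant = "core"
    stabilizer: StabilizerParams | None = None
    inputs: tuple[InputSpec, ...] = ()
    # external production modifier on SNAIL mRNA (used for RA / TGF-beta
    # co-treatment); 1.0 means untreated
    snail_mrna_production_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_mir200", "g_zeb_mrna", "g_zeb", "g_mir34",
                     "g_snail_mrna", "g_snail", "k_mir200", "k_zeb_mrna",
                     "k_zeb", "k_mir34", "k_snail_mrna", "k_snail"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if (self.variant != "core") != (self.stabilizer is not None):
            raise ValueError("stabilizer parameters must be set iff variant != core")
        if self.snail_mrna_production_factor <= 0:
            raise ValueError("production factor must be positive")

    @property
    def species(self) -> tuple[str, ...]:
        return CORE_SPECIES if self.variant == "core" else CORE_SPECIES + ("x",)

    @property
    def n_species(self) -> int:
        return len(self.species)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        d = dict(d)
        for key in ("zeb_on_mir200", "snail_on_mir200", "zeb_on_zeb_mrna",
                    "snail_on_zeb_mrna", "zeb_on_mir34", "snail_on_mir34",
                    "isig_on_snail_mrna", "snail_on_snail_mrna"):
            if key in d and isinstance(d[key], dict):
                d[key] = HillLink(**d[key])
        for key in ("mir200_zeb", "mir34_snail"):
            if key in d and isinstance(d[key], dict):
                v = dict(d[key])
                for f in ("l", "gm", "gu"):
                    v[f] = tuple(v[f])
                d[key] = MicroRNABindings(**v)
        if d.get("stabilizer") is not None and isinstance(d["stabilizer"], dict):
            s = dict(d["stabilizer"])
            for f in ("zeb_on_x", "x_on_zeb_mrna"):
                if isinstance(s[f], dict):
                    s[f] = HillLink(**s[f])
            d["stabilizer"] = StabilizerParams(**s)
        if "inputs" in d:
            d["inputs"] = tuple(
                InputSpec(**i) if isinstance(i, dict) else i for i in d["inputs"]
            )
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_production_factor(self, factor: float) -> "CircuitParams":
        """Copy of the parameter set with SNAIL-mRNA production scaled."""
        d = self.to_dict()
        d["snail_mrna_production_factor"] = factor
        return CircuitParams.from_dict(d)


def core_params() -> CircuitParams:
    """Baseline tri-stable parameter set of the ternary switch."""
    return CircuitParams()


def grhl2_params() -> CircuitParams:
    """Core circuit coupled to GRHL2 (moderate hybrid-state stabilization).

    The coupling strengths are calibrated so the hybrid-branch Isig interval
    widens severalfold relative to the core circuit (see docs/methods.md).
    """
    return CircuitParams(
        variant="grhl2",
        stabilizer=StabilizerParams(
            g=5000.0,
            k=0.1,
            zeb_on_x=HillLink(250000.0, 2, 0.1),
            x_on_zeb_mrna=HillLink(20000.0, 2, 0.55),
        ),
    )


def dnp63a_params() -> CircuitParams:
    """Core circuit coupled to dNP63a (strong hybrid-state stabilization)."""
    return CircuitParams(
        variant="dnp63a",
        stabilizer=StabilizerParams(
            g=5000.0,
            k=0.1,
            zeb_on_x=HillLink(200000.0, 2, 0.1),
            x_on_zeb_mrna=HillLink(20000.0, 2, 0.5),
        ),
    )


def params_for_variant(variant: Variant) -> CircuitParams:
    return {"core": core_params, "grhl2": grhl2_params, "dnp63a": dnp63a_params}[variant]()
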