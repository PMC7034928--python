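"""Run configuration: a simulation experiment as a serializable object.

A run is a pure function of its :class:`RunConfig` — circuit variant,
noise and rate specifications, initial condition, protocol and seeds are
all captured, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .bifurcation import BranchTable, scan_bifurcation
from .params import CircuitParams, params_for_variant
from .partitioning import NoiseSpec
from .population import RateSpec
from .protocols import (
    DoseEvent,
    DrugRegimen,
    ExogenousInputs,
    Protocol,
    ReplicateSummary,
    apply_exogenous_inputs,
    default_dose,
    run_replicates,
)

__all__ = ["RunConfig", "get_table", "clear_table_cache"]

# branch tables are expensive; cache per (parameter set repr)
_TABLE_CACHE: dict[str, BranchTable] = {}


def get_table(params: CircuitParams) -> BranchTable:
    key = repr(params.to_dict())
    if key not in _TABLE_CACHE:
        ref = None
        if params.snail_mrna_production_factor != 1.0:
            # treated circuits can lose branches; label them against the
            # untreated variant's classification cutoffs
            ref = get_table(params.with_production_factor(1.0)).thresholds
        _TABLE_CACHE[key] = scan_bifurcation(params, reference_thresholds=ref)
    return _TABLE_CACHE[key]


def clear_table_cache() -> None:
    _TABLE_CACHE.clear()


@dataclass
class RunConfig:
    """Everything needed to reproduce one replicate experiment."""

    variant: str = "core"
    params_file: str | None = None
    # noise
    eta: float = 2.7e4
    cv_species: float = 0.0
    mir34_mode: str = "off"
    convention: str = "birth"
    # rates
    doubling_time: float | dict = 38.0
    death_rate: float | dict = 0.005
    carrying_capacity: int = 10000
    # initial condition
    init_mode: str = "lognormal-mix"
    n0: int = 500
    isig_median: float = 2.0e4
    isig_cv: float = 1.0
    # schedule
    duration_days: float = 14.0
    sample_interval_h: float = 24.0
    n_replicates: int = 16
    base_seed: int = 0
    # protocol
    doses: list[dict] = field(default_factory=list)  # {"day": d, "d_isig": x}
    hysteresis: dict | None = None  # {"n_up": 10, "n_down": 10, "dose": null}
    drug: dict | None = None  # DrugRegimen fields, targets as list
    ra_um: float = 0.0
    tgfb_ng_ml: float = 0.0

    # -- derived objects -------------------------------------------------

    def circuit_params(self) -> CircuitParams:
        p = (
            CircuitParams.load(self.params_file)
            if self.params_file
            else params_for_variant(self.variant)
        )
        if self.ra_um or self.tgfb_ng_ml:
            p = apply_exogenous_inputs(
                p, ExogenousInputs(ra_um=self.ra_um, tgfb_ng_ml=self.tgfb_ng_ml)
            )
        return p

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(
            eta=self.eta,
            cv_species=self.cv_species,
            mir34_mode=self.mir34_mode,
            convention=self.convention,
        )

    def rate_spec(self) -> RateSpec:
        return RateSpec(
            doubling_time=self.doubling_time,
            death_rate=self.death_rate,
            carrying_capacity=self.carrying_capacity,
        )

    def table(self) -> BranchTable:
        return get_table(self.circuit_params())

    def protocol_factory(self, table: BranchTable):
        """None, or a per-replicate factory binding protocol hooks."""
        doses = [DoseEvent(24.0 * d["day"], d["d_isig"]) for d in self.doses]
        if self.hysteresis is not None:
            h = dict(self.hysteresis)
            dose = h.get("dose") or default_dose(table)
            n_up, n_down = h.get("n_up", 10), h.get("n_down", 10)
            doses += [DoseEvent(24.0 * k, dose) for k in range(n_up)]
            doses += [DoseEvent(24.0 * (n_up + k), -dose) for k in range(n_down)]
        drug = None
        if self.drug is not None:
            dd = dict(self.drug)
            dd["targets"] = frozenset(dd["targets"])
            drug = DrugRegimen(**dd)
        if not doses and drug is None:
            return None
        return lambda pop: Protocol(doses=list(doses), drug=drug)

    # -- execution -------------------------------------------------------

    def run(self) -> ReplicateSummary:
        table = self.table()
        return run_replicates(
            table,
            self.n_replicates,
            self.base_seed,
            init_mode=self.init_mode,
            n0=self.n0,
            duration_days=self.duration_days,
            rates=self.rate_spec(),
            noise=self.noise_spec(),
            protocol_factory=self.protocol_factory(table),
            median=self.isig_median,
            cv=self.isig_cv,
            sample_interval=self.sample_interval_h,
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise ValueError(f"invalid config {path}: {exc}") from None

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
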