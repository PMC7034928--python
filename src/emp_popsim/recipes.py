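"""Canned experiment recipes reproducing each figure's protocol.

Every recipe runs end-to-end from one CLI command at a scaled-down desk
default (8 replicates, carrying capacity 5000); ``full=True`` switches to
the published scale (16 replicates, carrying capacity 10000).  Outputs are
CSV tables plus a JSON summary per recipe.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, get_table
from .io import records_frame, write_summary_json
from .params import params_for_variant
from .partitioning import NoiseSpec
from .population import RateSpec, init_population, simulate, tally_divisions
from .protocols import DrugRegimen, run_treatment

__all__ = ["RECIPES", "run_recipe", "recipe_names"]


def _scale(full: bool) -> tuple[int, int]:
    return (16, 10000) if full else (8, 5000)


def _base(full: bool, seed: int, **kw) -> RunConfig:
    reps, K = _scale(full)
    return RunConfig(n_replicates=reps, carrying_capacity=K, base_seed=seed, **kw)


def _run_set(configs: list[tuple[str, RunConfig]], outdir: Path, tally: bool = False):
    outdir.mkdir(parents=True, exist_ok=True)
    index = []
    for label, cfg in configs:
        summary = cfg.run()
        df = summary.to_frame()
        df.to_csv(outdir / f"{label}_trajectory.csv", index=False)
        records = [r for run in summary.records for r in run]
        extra = {}
        if tally and records:
            tal = tally_divisions(records)
            tal.to_csv(outdir / f"{label}_tally.csv")
            extra["tally_csv"] = f"{label}_tally.csv"
        write_summary_json(outdir / f"{label}_summary.json", summary,
                           config=cfg, records=records if tally else None)
        index.append({"label": label, **extra})
    (outdir / "index.json").write_text(json.dumps(index, indent=1))


def _fig2a(outdir, full, seed, etas=(1e4, 2e4, 3e4, 4e4)):
    cfgs = [
        (f"eta{int(eta):d}", _base(full, seed, eta=eta, duration_days=56.0))
        for eta in etas
    ]
    _run_set(cfgs, outdir, tally=True)


def _fig2b(outdir, full, seed, etas=(1e4, 2e4, 3e4, 4e4)):
    cfgs = [
        (f"eta{int(eta):d}", _base(full, seed, eta=eta, duration_days=56.0))
        for eta in etas
    ]
    _run_set(cfgs, outdir)


def _fig2c(outdir, full, seed, doubling_times=(19.0, 38.0, 76.0)):
    cfgs = [
        (f"td{int(td):d}", _base(full, seed, eta=1e4, doubling_time=td,
                                 duration_days=56.0))
        for td in doubling_times
    ]
    _run_set(cfgs, outdir)


def _fig3(outdir, full, seed, eta=2.7e4):
    cfgs = [
        (mode, _base(full, seed, eta=eta, init_mode=f"pure-{mode}",
                     duration_days=14.0))
        for mode in "EHM"
    ]
    _run_set(cfgs, outdir)


def _fig3b(outdir, full, seed, eta=2.5e4):
    cfgs = [
        ("hybrid_mir34", _base(full, seed, eta=eta, init_mode="pure-H",
                               mir34_mode="zero-one", duration_days=14.0)),
        ("hybrid_baseline", _base(full, seed, eta=2.7e4, init_mode="pure-H",
                                  duration_days=14.0)),
    ]
    _run_set(cfgs, outdir)


def _fig4(outdir, full, seed, eta=2.7e4):
    cfg = _base(full, seed, eta=eta, init_mode="pure-E", duration_days=20.0,
                hysteresis={"n_up": 10, "n_down": 10})
    _run_set([("hysteresis", cfg)], outdir)
    # hysteresis loop table: fractions on the up leg vs the down leg
    summary = cfg.run()
    days = summary.times / 24.0
    rows = []
    for j, day in enumerate(days):
        leg = "up" if day <= 10 else "down"
        row = {"day": day, "leg": leg,
               "cumulative_doses": min(day, 10) - max(0.0, day - 10)}
        for k in "EHM":
            row[f"frac_{k}"] = summary.mean_fractions[k][j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "hysteresis_loop.csv", index=False)


def _fig5(outdir, full, seed, eta=2.7e4):
    cfgs = [
        (variant, _base(full, seed, variant=variant, eta=eta,
                        init_mode="pure-H", duration_days=14.0))
        for variant in ("core", "grhl2", "dnp63a")
    ]
    _run_set(cfgs, outdir, tally=True)


def _fig6(outdir, full, seed, eta=2.7e4):
    regimens = [(0.0, 0.0), (5.0, 0.0), (5.0, 5.0), (5.0, 0.5)]
    cfgs = [
        (f"ra{ra:g}_tgfb{tg:g}", _base(full, seed, eta=eta, init_mode="pure-E",
                                       duration_days=14.0, ra_um=ra,
                                       tgfb_ng_ml=tg))
        for ra, tg in regimens
    ]
    _run_set(cfgs, outdir)


_FIG7_REGIMENS = [
    ("E",), ("H",), ("M",), ("E", "H"), ("M", "H"), ("E", "M"), ("E", "H", "M"),
]


def _fig7(outdir, full, seed, concentration=2e4, treat_days=28.0):
    """Percent change in tumor size under phenotype-targeted regimens."""
    outdir.mkdir(parents=True, exist_ok=True)
    reps, K = _scale(full)
    table = get_table(params_for_variant("core"))
    rates = RateSpec(carrying_capacity=K)
    noise = NoiseSpec(eta=2.7e4)
    rows = []
    for targets in _FIG7_REGIMENS:
        pcts, finals = [], []
        for i, ss in enumerate(np.random.SeedSequence(seed).spawn(reps)):
            rng = np.random.default_rng(ss)
            pop = init_population(500, "lognormal-mix", table, rng,
                                  rates=rates, noise=noise)
            simulate(pop, 14 * 24.0, rng=rng, record_divisions=False)  # establish
            regimen = DrugRegimen(frozenset(targets), concentration)
            pct, fracs, _ = run_treatment(pop, regimen, treat_days, rng)
            pcts.append(pct)
            finals.append(fracs)
        rows.append({
            "targets": "+".join(targets),
            "pct_change_mean": float(np.mean(pcts)),
            "pct_change_sd": float(np.std(pcts)),
            **{f"frac_{k}_final": float(np.mean([f[k] for f in finals]))
               for k in "EHM"},
        })
    pd.DataFrame(rows).to_csv(outdir / "drug_regimens.csv", index=False)


def _fig8(outdir, full, seed, concentrations=(5e3, 1e4, 2e4, 4e4)):
    """Composition after co-targeting E and M at varying doses."""
    outdir.mkdir(parents=True, exist_ok=True)
    reps, K = _scale(full)
    table = get_table(params_for_variant("core"))
    rates = RateSpec(carrying_capacity=K)
    noise = NoiseSpec(eta=2.7e4)
    rows = []
    for conc in concentrations:
        finals, pcts = [], []
        for ss in np.random.SeedSequence(seed).spawn(reps):
            rng = np.random.default_rng(ss)
            pop = init_population(500, "pure-E", table, rng,
                                  rates=rates, noise=noise)
            simulate(pop, 14 * 24.0, rng=rng, record_divisions=False)
            pct, fracs, _ = run_treatment(
                pop, DrugRegimen(frozenset("EM"), conc), 28.0, rng)
            finals.append(fracs)
            pcts.append(pct)
        rows.append({
            "concentration": conc,
            "pct_change_mean": float(np.mean(pcts)),
            **{f"frac_{k}_final": float(np.mean([f[k] for f in finals]))
               for k in "EHM"},
        })
    pd.DataFrame(rows).to_csv(outdir / "em_cotarget.csv", index=False)


def _s1(outdir, full, seed):
    cfgs = (
        [(f"eta{int(e):d}", _base(full, seed, eta=e, duration_days=28.0))
         for e in (0.0, 4e4)]
        + [(f"td{int(td):d}", _base(full, seed, eta=1e4, doubling_time=td,
                                    duration_days=28.0)) for td in (19.0, 76.0)]
        + [(f"d{d:g}", _base(full, seed, eta=1e4, death_rate=d,
                             duration_days=28.0)) for d in (5e-4, 1.5e-2)]
    )
    _run_set(cfgs, outdir)


def _s13(outdir, full, seed, eta=2.5e4):
    # the all-species mode relaxes the circuit ODEs at every division, so
    # this recipe runs at a reduced population scale in either mode
    kw = dict(eta=eta, init_mode="pure-H", mir34_mode="zero-one",
              duration_days=10.0)
    cfgs = [
        ("isig_only", replace(_base(full, seed, **kw),
                              n0=200, carrying_capacity=1000)),
        ("all_species", replace(_base(full, seed, cv_species=0.25, **kw),
                                n0=200, carrying_capacity=1000)),
    ]
    _run_set(cfgs, outdir)


def _s14(outdir, full, seed, eta=2.5e4):
    cfgs = [
        (mode, _base(full, seed, eta=eta, init_mode="pure-H",
                     mir34_mode=mode, duration_days=14.0))
        for mode in ("zero-one", "zero-double")
    ]
    _run_set(cfgs, outdir)


RECIPES = {
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig3": _fig3,
    "fig3b": _fig3b,
    "fig4": _fig4,
    "fig5": _fig5,
    "fig6": _fig6,
    "fig7": _fig7,
    "fig8": _fig8,
    "s1": _s1,
    "s13": _s13,
    "s14": _s14,
}


def recipe_names() -> list[str]:
    return sorted(RECIPES)


def run_recipe(name: str, outdir, full: bool = False, seed: int = 0, **kw) -> Path:
    """Run one figure recipe; returns the output directory."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; available: {recipe_names()}")
    outdir = Path(outdir)
    RECIPES[name](outdir, full, seed, **kw)
    return outdir
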