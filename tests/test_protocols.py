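"""Interventions: dosing, drugs, co-treatment, replicates, fitting."""

import numpy as np
import pandas as pd
import pytest

from emp_popsim.params import core_params
from emp_popsim.partitioning import NoiseSpec
from emp_popsim.population import RateSpec, init_population, simulate
from emp_popsim.protocols import (
    DoseEvent,
    DrugRegimen,
    ExogenousInputs,
    apply_dose,
    apply_exogenous_inputs,
    default_dose,
    drug_multiplier,
    fit_parameter,
    run_replicates,
    run_treatment,
)


class TestApplyDose:
    def test_zero_dose_is_identity(self, core_table, rng):
        pop = init_population(50, "lognormal-mix", core_table, rng)
        before = sorted((c.branch, c.isig) for c in pop.cells())
        apply_dose(pop, DoseEvent(0.0, 0.0), core_table)
        after = sorted((c.branch, c.isig) for c in pop.cells())
        assert before == after

    def test_large_dose_drives_E_to_M(self, core_table, rng):
        pop = init_population(50, "pure-E", core_table, rng)
        apply_dose(pop, DoseEvent(0.0, 2.0e5), core_table)
        assert pop.counts()["M"] == 50

    def test_withdrawal_clamps_at_zero(self, core_table, rng):
        pop = init_population(50, "pure-E", core_table, rng)
        apply_dose(pop, DoseEvent(0.0, -1.0e9), core_table)
        assert all(c.isig == 0.0 for c in pop.cells())
        assert pop.counts()["E"] == 50


class TestDrugMultiplier:
    def test_zero_concentration_inert(self):
        reg = DrugRegimen(frozenset("E"), 0.0)
        for k in "EHM":
            assert drug_multiplier(reg, k) == 1.0

    def test_untargeted_unaffected(self):
        reg = DrugRegimen(frozenset("E"), 1e6)
        assert drug_multiplier(reg, "M") == 1.0

    def test_saturation_at_fold_change(self):
        reg = DrugRegimen(frozenset("M"), 1e9, lam_d=20.0)
        assert drug_multiplier(reg, "M") == pytest.approx(20.0, rel=1e-3)

    def test_inert_drug_identical_to_control(self, core_table):
        """Concentration 0 gives a byte-identical stochastic trajectory."""
        outs = []
        for conc in (None, 0.0):
            rng = np.random.default_rng(8)
            pop = init_population(150, "lognormal-mix", core_table, rng,
                                  rates=RateSpec(carrying_capacity=1200))
            simulate(pop, 7 * 24.0, rng=rng, record_divisions=False)
            if conc is None:
                traj, _ = simulate(pop, 7 * 24.0, rng=rng,
                                   record_divisions=False)
            else:
                _, _, traj = run_treatment(
                    pop, DrugRegimen(frozenset("EM"), conc), 7.0, rng)
            outs.append(traj.total)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_high_dose_single_target_shifts_composition(self, core_table):
        """Killing E leaves an M-dominated population of similar size."""
        rng = np.random.default_rng(9)
        rates = RateSpec(carrying_capacity=2000)
        pop = init_population(300, "lognormal-mix", core_table, rng,
                              rates=rates, noise=NoiseSpec(eta=2.7e4))
        simulate(pop, 14 * 24.0, rng=rng, record_divisions=False)
        pct, fracs, _ = run_treatment(
            pop, DrugRegimen(frozenset("E"), 5e4), 28.0, rng)
        assert fracs["M"] > 0.8
        assert pct > -50.0  # tumor size not substantially reduced


class TestExogenous:
    def test_zero_concentrations_identity(self):
        p = core_params()
        assert apply_exogenous_inputs(p, ExogenousInputs()) is p

    def test_factor_anchors(self):
        """5 uM RA blocks; +5 ng/ml TGF-beta restores; +0.5 is partial."""
        f_ra = ExogenousInputs(ra_um=5.0).factor()
        f_both = ExogenousInputs(ra_um=5.0, tgfb_ng_ml=5.0).factor()
        f_partial = ExogenousInputs(ra_um=5.0, tgfb_ng_ml=0.5).factor()
        assert f_ra < 0.2
        assert 0.9 < f_both < 1.6
        assert 0.6 < f_partial < 1.0

    def test_ra_blocks_emt_structurally(self):
        """Saturating RA leaves a single epithelial branch at any signal."""
        from emp_popsim.config import get_table

        p = apply_exogenous_inputs(core_params(), ExogenousInputs(ra_um=5.0))
        table = get_table(p)
        assert set(table.branches) == {"E"}
        assert not np.isfinite(table.branches["E"].hi)

    def test_negative_concentration_errors(self):
        with pytest.raises(ValueError):
            apply_exogenous_inputs(core_params(), ExogenousInputs(ra_um=-1.0))


class TestHysteresisDose:
    def test_default_dose_traverses_window(self, core_table):
        dose = default_dose(core_table)
        saddles = [core_table.branches["M"].lo, core_table.branches["H"].hi]
        assert 10 * dose > max(saddles) - min(saddles)


class TestRunReplicates:
    def test_single_run_zero_sd(self, core_table):
        s = run_replicates(core_table, 1, 3, duration_days=3.0, n0=100,
                           rates=RateSpec(carrying_capacity=500))
        for k in "EHM":
            assert np.all(s.sd_fractions[k] == 0.0)

    def test_deterministic_given_seed(self, core_table):
        a = run_replicates(core_table, 3, 11, duration_days=3.0, n0=100,
                           rates=RateSpec(carrying_capacity=500))
        b = run_replicates(core_table, 3, 11, duration_days=3.0, n0=100,
                           rates=RateSpec(carrying_capacity=500))
        for k in "EHM":
            np.testing.assert_array_equal(a.mean_fractions[k], b.mean_fractions[k])

    def test_requires_positive_runs(self, core_table):
        with pytest.raises(ValueError):
            run_replicates(core_table, 0, 1)


def _tiny_reference():
    return pd.DataFrame([
        {"day": 3, "frac_E": 0.8, "frac_H": 0.05, "frac_M": 0.15,
         "initial_condition": "pure-E"},
        {"day": 3, "frac_E": 0.3, "frac_H": 0.3, "frac_M": 0.4,
         "initial_condition": "pure-H"},
    ])


class TestFitParameter:
    def test_empty_grid_errors(self, core_table):
        with pytest.raises(ValueError):
            fit_parameter(_tiny_reference(), [], "eta", lambda: core_table)

    def test_malformed_reference_errors(self, core_table):
        bad = pd.DataFrame({"day": [1], "frac_E": [0.5]})
        with pytest.raises(ValueError):
            fit_parameter(bad, [1e4], "eta", lambda: core_table)

    def test_row_order_invariance(self, core_table):
        ref = _tiny_reference()
        kw = dict(n_runs=2, n0=100, rates=RateSpec(carrying_capacity=500))
        _, c1 = fit_parameter(ref, [1e4, 3e4], "eta", lambda: core_table, **kw)
        _, c2 = fit_parameter(ref.iloc[::-1].reset_index(drop=True),
                              [1e4, 3e4], "eta", lambda: core_table, **kw)
        pd.testing.assert_frame_equal(c1, c2)
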