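"""Unit tests for the circuit right-hand side and steady-state machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emp_popsim.circuit import (
    I_ZEB_MRNA,
    PhenotypeThresholds,
    classify_phenotype,
    circuit_jacobian,
    circuit_rhs,
    find_stable_states,
    is_stable_state,
    relax_to_steady_state,
    shifted_hill,
)
from emp_popsim.params import CircuitParams, core_params


class TestShiftedHill:
    @pytest.mark.parametrize(
        "X, X0, n, lam, expected",
        [
            (0.0, 123.0, 2, 4.0, 1.0),  # unperturbed baseline
            (100.0, 100.0, 2, 4.0, 2.5),  # midpoint gives (1+lam)/2
            (1e12, 100.0, 2, 0.1, 0.1),  # saturation at lam
            (1e12, 100.0, 2, 7.5, 7.5),
        ],
    )
    def test_limits(self, X, X0, n, lam, expected):
        assert shifted_hill(X, X0, n, lam) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            shifted_hill(np.nan, 1.0, 1, 2.0)
        with pytest.raises(ValueError):
            shifted_hill(np.inf, 1.0, 1, 2.0)

    @given(
        X=st.floats(0, 1e7),
        lam=st.floats(0.01, 20).filter(lambda v: abs(v - 1) > 1e-3),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_between_1_and_lam(self, X, lam):
        v = shifted_hill(X, 1e4, 2, lam)
        lo, hi = sorted((1.0, lam))
        assert lo - 1e-9 <= v <= hi + 1e-9

    def test_monotone(self):
        x = np.linspace(0, 1e6, 200)
        up = shifted_hill(x, 5e4, 2, 10.0)
        dn = shifted_hill(x, 5e4, 2, 0.1)
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(dn) <= 0)


class TestRHS:
    def test_zero_state_pure_production(self):
        """No degradation at zero: transcripts grow; proteins await mRNA."""
        from emp_popsim.circuit import I_SNAIL, I_ZEB

        p = core_params()
        f = circuit_rhs(np.zeros(6), 1e4, p)
        assert np.all(f >= 0)
        transcribed = np.ones(6, dtype=bool)
        transcribed[[I_ZEB, I_SNAIL]] = False  # translation needs mRNA
        assert np.all(f[transcribed] > 0)

    def test_degradation_linearity(self):
        """Doubling all k doubles the degradation part of each derivative."""
        p1 = core_params()
        d = p1.to_dict()
        for key in d:
            if key.startswith("k_"):
                d[key] *= 2.0
        p2 = CircuitParams.from_dict(d)
        y = np.array([2e4, 50.0, 5e3, 1.2e4, 600.0, 1.5e5])
        f1 = circuit_rhs(y, 3e4, p1)
        f2 = circuit_rhs(y, 3e4, p2)
        k = np.array([p1.k_mir200, p1.k_zeb_mrna, p1.k_zeb, p1.k_mir34,
                      p1.k_snail_mrna, p1.k_snail])
        np.testing.assert_allclose(f1 - f2, k * y, rtol=1e-10)

    def test_variant_dimension_mismatch_errors(self):
        from emp_popsim.params import grhl2_params

        with pytest.raises(ValueError):
            circuit_rhs(np.zeros(6), 1e4, grhl2_params())
        with pytest.raises(ValueError):
            circuit_rhs(np.zeros(7), 1e4, core_params())


def _brute_force_attractors(isig, p, n_grid=3):
    """Independent oracle: relaxation from a dense deterministic grid."""
    finals = []
    scales = {
        0: (1e2, 4e4), 1: (1.0, 2e3), 2: (1e2, 1.5e6),
        3: (1e2, 3e4), 4: (1.0, 3e3), 5: (1e3, 8e5),
    }
    pts = [np.geomspace(lo, hi, n_grid) for lo, hi in scales.values()]
    # a deterministic sparse sample of the full grid (diagonal + corners)
    for j in range(n_grid):
        finals.append(relax_to_steady_state([pts[i][j] for i in range(6)], isig, p))
    for corner in ([0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1],
                   [1, 0, 0, 1, 0, 0], [0, 1, 1, 0, 1, 1]):
        y0 = [pts[i][-1] if c else pts[i][0] for i, c in enumerate(corner)]
        finals.append(relax_to_steady_state(y0, isig, p))
    uniq = []
    for y in finals:
        if not any(abs(y[I_ZEB_MRNA] - u[I_ZEB_MRNA]) <
                   0.05 * (1 + abs(u[I_ZEB_MRNA])) for u in uniq):
            uniq.append(y)
    return sorted(uniq, key=lambda y: y[I_ZEB_MRNA])


class TestStableStates:
    def test_monostable_epithelial_at_zero_signal(self):
        p = core_params()
        states = find_stable_states(0.0, p)
        oracle = _brute_force_attractors(0.0, p)
        assert len(states) == len(oracle) == 1
        np.testing.assert_allclose(states[0][0], oracle[0], rtol=1e-3)
        assert states[0][0][I_ZEB_MRNA] < 100  # low ZEB mRNA: epithelial

    def test_monostable_mesenchymal_at_high_signal(self):
        p = core_params()
        states = find_stable_states(1.2e5, p)
        oracle = _brute_force_attractors(1.2e5, p)
        assert len(states) == len(oracle) == 1
        assert states[0][0][I_ZEB_MRNA] > 600

    def test_three_states_in_tristable_window(self):
        p = core_params()
        states = find_stable_states(52000.0, p)
        assert len(states) == 3
        for y, _ in states:
            assert is_stable_state(y, 52000.0, p)

    def test_states_satisfy_rhs_and_stability(self):
        p = core_params()
        for isig in (0.0, 3e4, 52000.0, 9e4):
            for y, _ in find_stable_states(isig, p):
                f = circuit_rhs(y, isig, p)
                assert np.max(np.abs(f) / (1 + np.abs(y))) < 1e-6
                eig = np.linalg.eigvals(circuit_jacobian(y, isig, p))
                assert np.max(eig.real) < 0

    def test_labels_with_thresholds(self):
        p = core_params()
        thr = PhenotypeThresholds(170.0, 600.0)
        states = find_stable_states(52000.0, p, thresholds=thr)
        assert [lab for _, lab in states] == ["E", "H", "M"]


class TestRelaxation:
    def test_fixed_point_is_invariant(self):
        p = core_params()
        y, _ = find_stable_states(3e4, p)[0]
        out = relax_to_steady_state(y, 3e4, p)
        np.testing.assert_allclose(out, y, rtol=1e-4)

    def test_same_signal_same_branch(self):
        """Continuity: relaxing a steady state at its own signal is a no-op."""
        p = core_params()
        states = find_stable_states(52000.0, p)
        for y, _ in states:
            out = relax_to_steady_state(y, 52000.0, p)
            assert abs(out[I_ZEB_MRNA] - y[I_ZEB_MRNA]) < 0.05 * (1 + y[I_ZEB_MRNA])

    def test_epithelial_state_past_saddle_leaves_branch(self, core_table):
        p = core_params()
        e = core_table.branches["E"]
        beyond = e.hi + 2000.0
        out = relax_to_steady_state(e.states[-1], beyond, p)
        assert out[I_ZEB_MRNA] > core_table.thresholds.lower  # no longer E

    def test_classification_invariant_to_solver_tolerance(self, core_table):
        p = core_params()
        thr = core_table.thresholds
        for isig in (1e4, 52000.0, 8e4):
            for y, _ in find_stable_states(isig, p):
                lab = classify_phenotype(y, thr)
                for tol in (1e-5, 1e-7):
                    out = relax_to_steady_state(1.01 * y, isig, p, tol=tol)
                    assert classify_phenotype(out, thr) == lab


class TestClassify:
    def test_zero_is_epithelial(self):
        thr = PhenotypeThresholds(170.0, 600.0)
        assert classify_phenotype(0.0, thr) == "E"

    def test_branch_levels_classify_correctly(self, core_table):
        thr = core_table.thresholds
        e_mz = core_table.branches["E"].mz_range[1]
        h_mz = np.mean(core_table.branches["H"].mz_range)
        m_mz = core_table.branches["M"].mz_range[0]
        assert classify_phenotype(e_mz, thr) == "E"
        assert classify_phenotype(h_mz, thr) == "H"
        assert classify_phenotype(m_mz, thr) == "M"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PhenotypeThresholds(600.0, 170.0)
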