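"""The ISA fixed-point engine against independent oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from apisa import (PlantSpec, isa_step, normalize, planted_expression,
                   run_seed, threshold_scores)


class TestNormalize:
    def test_row_example(self):
        P = normalize(np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]]))
        assert np.allclose(P.e_c[0], [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_invariants(self, rng):
        P = normalize(rng.normal(size=(6, 9)))
        assert np.allclose(P.e_c.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(P.e_c.std(axis=1, ddof=1), 1, atol=1e-9)
        assert np.allclose(P.e_g.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(P.e_g.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_idempotent(self, rng):
        P = normalize(rng.normal(size=(5, 7)))
        again = normalize(P.e_c)
        assert np.allclose(again.e_c, P.e_c, atol=1e-12)

    def test_constant_column_named(self, small_expression):
        E = small_expression.copy()
        E["g2"] = 5.0
        with pytest.raises(ValueError, match="g2"):
            normalize(E)


class TestThresholdScores:
    def test_single_outlier_kept_at_t1(self):
        kept = threshold_scores(np.array([0.0, 0.0, 0.0, 10.0]), 1.0)
        assert list(kept) == [False, False, False, True]  # z = 1.5

    def test_single_outlier_dropped_at_t2(self):
        kept = threshold_scores(np.array([0.0, 0.0, 0.0, 10.0]), 2.0)
        assert not kept.any()  # 1.5 < 2

    def test_constant_scores_warn_and_empty(self):
        with pytest.warns(UserWarning):
            kept = threshold_scores(np.ones(5), 1.0)
        assert not kept.any()

    def test_updown_keeps_both_tails(self):
        scores = np.array([-10.0, 0.0, 0.0, 0.0, 10.0])
        up = threshold_scores(scores, 1.0, "up")
        both = threshold_scores(scores, 1.0, "updown")
        assert up.sum() == 1 and both.sum() == 2

    @given(
        scores=arrays(np.float64, st.integers(4, 20),
                      elements=st.floats(-50, 50)),
        t1=st.floats(0.0, 2.0), dt=st.floats(0.0, 2.0),
    )
    def test_monotone_in_threshold(self, scores, t1, dt):
        # the kept set at a higher threshold is nested in the lower one
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo = threshold_scores(scores, t1)
            hi = threshold_scores(scores, t1 + dt)
        assert not (hi & ~lo).any()


def loop_scores(X_c, X_g, c):
    """Independent double-loop computation of both score vectors."""
    m, n = X_c.shape
    sel = [i for i in range(m) if c[i]]
    gene_scores = np.array([
        sum(X_c[i, j] for i in sel) / len(sel) for j in range(n)
    ])
    return gene_scores


class TestIsaStep:
    def test_scores_match_loop_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(8, 12))
            P = normalize(X)
            c = rng.random(8) < 0.4
            if not c.any():
                c[0] = True
            expected = loop_scores(P.e_c, P.e_g, c)
            got = P.e_c[c].mean(axis=0)
            assert np.allclose(got, expected, atol=1e-12)
            g, c_next = isa_step(P, c, 0.5, 0.5)
            if g.any():
                sample_expected = np.array([
                    sum(P.e_g[i, j] for j in np.flatnonzero(g)) / g.sum()
                    for i in range(8)
                ])
                kept = threshold_scores(sample_expected, 0.5)
                assert (c_next == kept).all()

    def test_empty_sample_vector_rejected(self, rng):
        P = normalize(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            isa_step(P, np.zeros(4, bool), 1.0, 1.0)

    def test_vanishes_under_null_at_t3(self, rng):
        vanished = 0
        trials = 200
        for _ in range(trials):
            P = normalize(rng.normal(size=(10, 20)))
            _, c_next = isa_step(P, np.ones(10, bool), 3.0, 3.0)
            vanished += c_next is None
        assert vanished / trials >= 0.95

    def test_recovers_planted_block_from_exact_seed(self):
        spec = PlantSpec(m=200, n=500, prevalences=(0.2, 0.8),
                         genes_per_module=60, delta=3.0)
        E, truth = planted_expression(spec, rng_seed=3)
        P = normalize(E)
        truth_samples = np.array([s in truth.modules[0][0] for s in E.index])
        truth_genes = np.array([g in truth.modules[0][1] for g in E.columns])
        g, c_next = isa_step(P, truth_samples, 1.5, 1.5)
        assert (g == truth_genes).all()
        assert (c_next == truth_samples).all()


class TestRunSeed:
    def test_fixed_point_seed_stays_put(self):
        spec = PlantSpec(m=200, n=500, prevalences=(0.2, 0.8),
                         genes_per_module=60, delta=3.0)
        E, truth = planted_expression(spec, rng_seed=3)
        P = normalize(E)
        fp = np.array([s in truth.modules[0][0] for s in E.index])
        res = run_seed(P, fp, 1.5, 1.5, min_stable=2)
        assert res is not None and res.converged
        assert res.n_iterations <= 3  # min_stable + 1
        assert set(res.sample_idx) == set(np.flatnonzero(fp))

    def test_two_sample_seed_recovers_planted_block(self, rng):
        spec = PlantSpec(m=200, n=500, prevalences=(0.2, 0.8),
                         genes_per_module=60, delta=3.0)
        E, truth = planted_expression(spec, rng_seed=5)
        P = normalize(E)
        members = np.flatnonzero(
            np.array([s in truth.modules[0][0] for s in E.index]))
        seed = np.zeros(200, bool)
        seed[rng.choice(members, 2, replace=False)] = True
        res = run_seed(P, seed, 1.5, 1.5)
        assert res is not None
        found_s = set(res.sample_idx)
        found_g = set(res.gene_idx)
        true_s = set(members)
        true_g = set(np.flatnonzero(
            np.array([g in truth.modules[0][1] for g in E.columns])))
        jac = lambda a, b: len(a & b) / len(a | b)
        assert jac(found_s, true_s) >= 0.9
        assert jac(found_g, true_g) >= 0.9

    def test_null_fixed_points_are_tiny(self, rng):
        # pure noise supports no large module: survivors have a handful of
        # samples, nothing at the planted-block scale
        for _ in range(20):
            P = normalize(rng.normal(size=(50, 100)))
            seed = np.zeros(50, bool)
            seed[rng.choice(50, 2, replace=False)] = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_seed(P, seed, 2.0, 2.0)
            if res is not None:
                assert len(res.sample_idx) <= 10

    def test_determinism(self, rng):
        X = rng.normal(size=(30, 40))
        X[:10, :10] += 3.0
        P = normalize(X)
        seed = np.zeros(30, bool)
        seed[[2, 5]] = True
        r1 = run_seed(P, seed, 1.5, 1.5)
        r2 = run_seed(P, seed, 1.5, 1.5)
        assert r1 is not None and r2 is not None
        assert (r1.sample_idx == r2.sample_idx).all()
        assert (r1.gene_idx == r2.gene_idx).all()

    def test_empty_seed_rejected(self, rng):
        P = normalize(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            run_seed(P, np.zeros(4, bool), 1.0, 1.0)

    def test_fixed_point_is_threshold_consistent(self):
        # re-running one step on a converged pair reproduces it exactly
        spec = PlantSpec(m=100, n=200, prevalences=(0.3, 0.7),
                         genes_per_module=40, delta=3.0)
        E, truth = planted_expression(spec, rng_seed=11)
        P = normalize(E)
        seed = np.zeros(100, bool)
        seed[[0, 1]] = True  # first two samples are in group 0
        res = run_seed(P, seed, 1.5, 1.2)
        assert res is not None
        c = np.zeros(100, bool)
        c[res.sample_idx] = True
        g, c_next = isa_step(P, c, 1.5, 1.2)
        assert set(np.flatnonzero(g)) == set(res.gene_idx)
        assert set(np.flatnonzero(c_next)) == set(res.sample_idx)
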