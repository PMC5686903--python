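"""Seed generation, AP-guided classification and apportionment."""

import numpy as np
import pytest

from apisa import (APResult, Seed, assign_thresholds, classify_seeds,
                   generate_seeds, largest_remainder, sample_seeds)
from apisa.seeds import SeedGroups


def ap_result(labels):
    labels = np.asarray(labels)
    exemplars = np.array([int(np.flatnonzero(labels == k)[0])
                          for k in range(labels.max() + 1)])
    return APResult(labels=labels, exemplars=exemplars, preference=0.0,
                    n_iterations=1, converged=True,
                    k_found=int(labels.max() + 1))


class TestGenerateSeeds:
    def test_sparsity_and_count(self):
        seeds = generate_seeds(m=20, n_seeds=100, sparsity=3, rng_seed=0)
        assert len(seeds) == 100
        assert all(len(s.support) == 3 for s in seeds)

    def test_full_sparsity_is_full_set(self):
        seeds = generate_seeds(m=5, n_seeds=3, sparsity=5, rng_seed=0)
        assert all(s.support == frozenset(range(5)) for s in seeds)

    def test_sparsity_above_m_rejected(self):
        with pytest.raises(ValueError):
            generate_seeds(m=4, n_seeds=1, sparsity=5)

    def test_inclusion_frequency_binomial(self):
        m, n_seeds, sparsity = 20, 10_000, 2
        seeds = generate_seeds(m, n_seeds, sparsity, rng_seed=1)
        counts = np.zeros(m)
        for s in seeds:
            for i in s.support:
                counts[i] += 1
        p = sparsity / m
        sd = np.sqrt(n_seeds * p * (1 - p))
        assert np.all(np.abs(counts - n_seeds * p) <= 3 * sd)

    def test_reproducible(self):
        a = generate_seeds(10, 50, 2, rng_seed=9)
        b = generate_seeds(10, 50, 2, rng_seed=9)
        assert a == b


class TestClassifySeeds:
    def test_rule_application(self):
        ap = ap_result([0, 0, 1, 1])
        seeds = [Seed({0, 1}, 4), Seed({1, 2}, 4), Seed({2, 3}, 4)]
        G = classify_seeds(seeds, ap)
        assert G.groups[0] == [seeds[0]]
        assert G.groups[1] == [seeds[2]]
        assert G.discarded_count == 1
        assert G.n_retained + G.discarded_count == 3

    def test_single_cluster_no_discards(self):
        ap = ap_result([0, 0, 0])
        seeds = generate_seeds(3, 50, 2, rng_seed=0)
        G = classify_seeds(seeds, ap)
        assert G.discarded_count == 0

    def test_retained_fraction_matches_sum_p_squared(self):
        # sparsity-2 seeds land in one cluster with prob ~ sum p_i^2
        m = 200
        sizes = [60, 30, 70, 30, 10]
        labels = np.repeat(np.arange(5), sizes)
        ap = ap_result(labels)
        n_seeds = 10_000
        seeds = generate_seeds(m, n_seeds, 2, rng_seed=2)
        G = classify_seeds(seeds, ap)
        p = np.array(sizes) / m
        expect = float((p ** 2).sum())
        sd = np.sqrt(expect * (1 - expect) / n_seeds)
        assert abs(G.n_retained / n_seeds - expect) <= 3 * sd

    def test_supports_stay_inside_their_cluster(self):
        labels = np.repeat([0, 1, 2], [5, 3, 2])
        ap = ap_result(labels)
        seeds = generate_seeds(10, 500, 2, rng_seed=3)
        G = classify_seeds(seeds, ap)
        for k, grp in G.groups.items():
            for s in grp:
                assert all(labels[i] == k for i in s.support)


class TestApportionment:
    def test_prevalence_quota_example(self):
        assert largest_remainder([0.30, 0.15, 0.35, 0.15, 0.05], 100) == \
            [30, 15, 35, 15, 5]

    def test_quotas_sum_to_total(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 8))
            w = rng.integers(1, 100, size=k)
            total = int(rng.integers(1, 200))
            q = largest_remainder(w, total)
            assert sum(q) == total
            assert all(x >= 0 for x in q)

    def test_monotone_in_weight(self, rng):
        for _ in range(50):
            w = rng.integers(1, 50, size=5)
            q = largest_remainder(w, 37)
            order = np.argsort(-w, kind="stable")
            qs = [q[i] for i in order]
            assert qs == sorted(qs, reverse=True)


class TestSampleSeeds:
    def _groups(self, sizes, cluster_sizes=None, m=100, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        groups = {}
        for k, sz in enumerate(sizes):
            groups[k] = [
                Seed(frozenset(int(x) for x in rng.choice(m, 2, False)), m)
                for _ in range(sz)
            ]
        return SeedGroups(groups=groups, discarded_count=0,
                          cluster_sizes=cluster_sizes or {})

    def test_quota_follows_cluster_prevalence(self):
        G = self._groups([300, 150, 350, 150, 50],
                         cluster_sizes={0: 30, 1: 15, 2: 35, 3: 15, 4: 5})
        sel = sample_seeds(G, 100, rng_seed=0)
        assert sel.group_sizes() == {0: 30, 1: 15, 2: 35, 3: 15, 4: 5}

    def test_total_equals_retained_is_identity(self):
        G = self._groups([5, 3])
        sel = sample_seeds(G, 8, rng_seed=0)
        assert sel.group_sizes() == {0: 5, 1: 3}
        assert set(sel.groups[0]) == set(G.groups[0])

    def test_deficit_reassigned_to_larger_groups(self):
        # group 1's cluster is huge but it retained only 2 seeds
        G = self._groups([50, 2], cluster_sizes={0: 10, 1: 90})
        sel = sample_seeds(G, 20, rng_seed=0)
        assert sel.group_sizes()[1] == 2
        assert sum(sel.group_sizes().values()) == 20

    def test_over_request_rejected(self):
        G = self._groups([2, 2])
        with pytest.raises(ValueError):
            sample_seeds(G, 10)

    def test_reproducible(self):
        G = self._groups([30, 20, 10])
        a = sample_seeds(G, 12, rng_seed=4)
        b = sample_seeds(G, 12, rng_seed=4)
        assert a.groups == b.groups


class TestAssignThresholds:
    def _groups(self, sizes):
        m = 50
        groups = {
            k: [Seed({i, (i + 1) % m}, m) for i in range(sz)]
            for k, sz in enumerate(sizes)
        }
        return SeedGroups(groups=groups, discarded_count=0)

    def test_historical_overrides_verbatim(self):
        G = assign_thresholds(self._groups([30, 15, 35, 15, 5]),
                              overrides=[1, 1.4, 0.9, 1.4, 2], t_c=1.6)
        t_gs = [G.group_thresholds[k][0] for k in sorted(G.group_thresholds)]
        assert t_gs == [1.0, 1.4, 0.9, 1.4, 2.0]
        assert all(v[1] == 1.6 for v in G.group_thresholds.values())

    def test_equal_sizes_all_midpoint(self):
        G = assign_thresholds(self._groups([4, 4, 4]), t_range=(1.0, 2.0))
        assert all(v[0] == pytest.approx(1.5)
                   for v in G.group_thresholds.values())

    def test_linear_rank_map(self):
        G = assign_thresholds(self._groups([40, 30, 20, 10, 5]),
                              t_range=(1.0, 2.0))
        t_gs = [G.group_thresholds[k][0] for k in sorted(G.group_thresholds)]
        assert t_gs == pytest.approx([1.0, 1.25, 1.5, 1.75, 2.0])

    def test_override_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_thresholds(self._groups([3, 3]), overrides=[1.0])
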