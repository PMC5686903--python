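"""Seed generation, AP-guided classification, subsampling and thresholds.

The ISA iteration is started from random sparse binary sample vectors
("seeds").  Here the affinity-propagation clustering of the samples acts as
prior knowledge: a seed is retained only if its whole support lies inside a
single AP cluster, and the retained seeds are grouped by that cluster.  A
fixed total is then drawn proportionally to group size (largest-remainder
apportionment), and each group receives its own gene threshold — larger
groups get smaller thresholds so their biclusters can grow, mirroring the
unequal prevalence of the underlying sample subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .ap import APResult

log = logging.getLogger(__name__)

__all__ = [
    "Seed",
    "SeedGroups",
    "generate_seeds",
    "classify_seeds",
    "sample_seeds",
    "assign_thresholds",
    "largest_remainder",
]


@dataclass(frozen=True)
class Seed:
    """Sparse binary sample-indicator vector, stored as its support."""

    support: frozenset
    m: int

    def __post_init__(self):
        object.__setattr__(self, "support", frozenset(self.support))
        if not (1 <= len(self.support) <= self.m):
            raise ValueError("seed support must satisfy 1 <= |support| <= m")
        if any(not (0 <= i < self.m) for i in self.support):
            raise ValueError("seed support index out of range")

    def as_bool(self) -> np.ndarray:
        v = np.zeros(self.m, dtype=bool)
        v[list(self.support)] = True
        return v


@dataclass
class SeedGroups:
    """Retained seeds partitioned by AP cluster, plus per-group thresholds."""

    groups: dict  # cluster label -> list[Seed]
    discarded_count: int
    group_thresholds: dict | None = None  # cluster label -> (t_g, t_c)
    cluster_sizes: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def group_sizes(self) -> dict:
        return {k: len(v) for k, v in self.groups.items()}


def generate_seeds(m: int, n_seeds: int, sparsity: int = 2,
                   rng_seed: int = 0) -> list:
    """Draw ``n_seeds`` seeds of exactly ``sparsity`` distinct samples each."""
    if not (1 <= sparsity <= m):
        raise ValueError(f"sparsity={sparsity} outside [1, m={m}]")
    rng = np.random.default_rng(rng_seed)
    return [
        Seed(frozenset(int(i) for i in rng.choice(m, size=sparsity,
                                                  replace=False)), m)
        for _ in range(n_seeds)
    ]


def classify_seeds(seeds: list, ap: APResult) -> SeedGroups:
    """Group seeds by AP cluster; discard seeds spanning several clusters."""
    labels = np.asarray(ap.labels)
    groups: dict = {int(k): [] for k in range(len(ap.exemplars))}
    discarded = 0
    for seed in seeds:
        sup = list(seed.support)
        labs = labels[sup]
        if np.all(labs == labs[0]):
            groups[int(labs[0])].append(seed)
        else:
            discarded += 1
    sizes = {int(k): int((labels == k).sum()) for k in groups}
    return SeedGroups(groups=groups, discarded_count=discarded,
                      cluster_sizes=sizes)


def largest_remainder(weights, total: int) -> list:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact shares, then hands the leftover units to the largest
    fractional remainders (ties broken toward the larger weight, then the
    lower index).  Quotas always sum to ``total``.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    shares = total * w / w.sum()
    quotas = np.floor(shares).astype(int)
    remainder = total - quotas.sum()
    order = sorted(
        range(len(w)),
        key=lambda i: (-(shares[i] - quotas[i]), -w[i], i),
    )
    for i in order[:remainder]:
        quotas[i] += 1
    return quotas.tolist()


def sample_seeds(G: SeedGroups, total: int, rng_seed: int = 0) -> SeedGroups:
    """Subsample ``total`` seeds across groups by largest-remainder quota.

    Quotas follow the AP cluster sizes (the subtype prevalences the seeds
    are meant to mirror) when known, falling back to the retained seed-group
    sizes.  Retained counts scale with the square of cluster prevalence, so
    apportioning by cluster size keeps rare subtypes represented.
    """
    if total > G.n_retained:
        raise ValueError(
            f"requested {total} seeds but only {G.n_retained} retained"
        )
    keys = sorted(G.groups)
    if G.cluster_sizes and sum(G.cluster_sizes.get(k, 0) for k in keys) > 0:
        sizes = [G.cluster_sizes.get(k, 0) for k in keys]
    else:
        sizes = [len(G.groups[k]) for k in keys]
    quotas = dict(zip(keys, largest_remainder(sizes, total)))
    # groups smaller than their quota hand the excess to the largest groups
    deficit = 0
    for k in keys:
        if quotas[k] > len(G.groups[k]):
            deficit += quotas[k] - len(G.groups[k])
            quotas[k] = len(G.groups[k])
    if deficit:
        log.warning("reassigning %d seed quota units to larger groups", deficit)
        for k in sorted(keys, key=lambda k: -len(G.groups[k])):
            room = len(G.groups[k]) - quotas[k]
            take = min(room, deficit)
            quotas[k] += take
            deficit -= take
            if deficit == 0:
                break
    rng = np.random.default_rng(rng_seed)
    out = {}
    for k in keys:
        grp = G.groups[k]
        idx = rng.choice(len(grp), size=quotas[k], replace=False)
        out[k] = [grp[int(i)] for i in sorted(idx)]
    return SeedGroups(groups=out, discarded_count=G.discarded_count,
                      group_thresholds=G.group_thresholds,
                      cluster_sizes=G.cluster_sizes)


def assign_thresholds(G: SeedGroups, t_range=(1.0, 2.0), t_c: float = 1.0,
                      overrides=None) -> SeedGroups:
    """Attach a (t_g, t_c) pair to every seed group.

    With ``overrides`` given (one t_g per group, in group order) they are
    used verbatim.  Otherwise t_g is a linear map of the group-size rank onto
    ``t_range``: the largest group gets the low end (big, permissive
    biclusters), the smallest the high end; ties average their ranks, so
    equal-sized groups share the midpoint.  ``t_c`` is constant across
    groups.
    """
    low, high = t_range
    if low > high:
        raise ValueError("t_range must satisfy low <= high")
    keys = sorted(G.groups)
    K = len(keys)
    if overrides is not None:
        if len(overrides) != K:
            raise ValueError(
                f"got {len(overrides)} threshold overrides for {K} groups"
            )
        t_gs = [float(t) for t in overrides]
    elif K == 1:
        t_gs = [0.5 * (low + high)]
    else:
        sizes = np.array([len(G.groups[k]) for k in keys], dtype=float)
        ranks = rankdata(-sizes, method="average")  # largest -> rank 1
        t_gs = [low + (r - 1.0) / (K - 1.0) * (high - low) for r in ranks]
    thresholds = {k: (t_g, float(t_c)) for k, t_g in zip(keys, t_gs)}
    return SeedGroups(groups=G.groups, discarded_count=G.discarded_count,
                      group_thresholds=thresholds,
                      cluster_sizes=G.cluster_sizes)
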