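"""The AP-ISA pipeline: AP clustering -> guided seeding -> per-seed ISA.

The three stages are:

1. Affinity propagation over the samples, tuned to K clusters (the number
   of subtypes expected, e.g. K = 5 for breast cancer).
2. Random sparse seed generation; seeds whose support spans more than one
   AP cluster are deleted, the rest grouped by cluster, subsampled
   proportionally to group size, and given per-group gene thresholds.
3. Every selected seed is iterated to an ISA fixed point under its group's
   thresholds; converged fixed points are pooled (identical fixed points
   merge, accumulating a basin count) and deduplicated by Jaccard overlap,
   keeping within each overlap component the fixed point with the largest
   basin.

`APISA` is the scikit-learn-style estimator; `run_apisa` the functional
wrapper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import isa, seeds as seeds_mod
from .ap import similarity_matrix, cluster_with_k
from .records import BiclusterRecord, BiclusterSet, combined_jaccard

log = logging.getLogger(__name__)

__all__ = ["APISAConfig", "APISA", "FixedPointPool", "run_apisa",
           "select_diverse", "APError"]


class APError(RuntimeError):
    """Affinity propagation could not deliver the requested K."""


@dataclass
class APISAConfig:
    """Run parameters for the full pipeline.

    Defaults follow the method's canonical operating point: K = 5 subtype
    clusters, 10,000 random seeds of sparsity 2, 100 seeds selected
    proportionally, gene thresholds spread over [1, 2] by group-size rank
    and a constant sample threshold of 1.0, all in score-sd units.
    """

    k: int = 5
    n_seeds: int = 10_000
    sparsity: int = 2
    total_selected: int = 100
    t_range: tuple = (1.0, 2.0)
    t_c: float = 1.0
    t_g_overrides: list | None = None
    direction: str = "up"
    max_iter: int = 100
    min_stable: int = 2
    dedup_jaccard: float = 0.8
    damping: float = 0.5
    ap_max_iter: int = 1000
    ap_conv_iter: int = 50
    tol_steps: int = 30
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "APISAConfig":
        cfg = cls(**d)
        if isinstance(cfg.t_range, list):
            cfg.t_range = tuple(cfg.t_range)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "APISAConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t_range"] = list(self.t_range)
        return d


@dataclass
class FixedPointPool:
    """Distinct ISA fixed points with the number of seeds in each basin."""

    records: list = field(default_factory=list)
    basin_counts: list = field(default_factory=list)


def select_diverse(pool: FixedPointPool, dedup_jaccard: float = 0.8) -> list:
    """Deduplicate a fixed-point pool by Jaccard-overlap components.

    Records are nodes; an edge joins two records whose combined Jaccard
    (on the tagged union of sample and gene memberships) exceeds
    ``dedup_jaccard``.  Within each connected component the record with the
    largest basin count survives (ties: more samples, then lexicographic
    id).  Output is sorted by basin count descending, then id.
    """
    recs = list(pool.records)
    basins = list(pool.basin_counts)
    G = nx.Graph()
    G.add_nodes_from(range(len(recs)))
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if combined_jaccard(recs[i], recs[j]) > dedup_jaccard:
                G.add_edge(i, j)
    survivors = []
    for comp in nx.connected_components(G):
        best = max(comp, key=lambda i: (basins[i], recs[i].n_samples,
                                        [-ord(c) for c in recs[i].id]))
        merged_basin = sum(basins[i] for i in comp)
        survivors.append((merged_basin, recs[best]))
    survivors.sort(key=lambda t: (-t[0], t[1].id))
    out = []
    for rank, (basin, rec) in enumerate(survivors, start=1):
        out.append(BiclusterRecord(
            id=f"B{rank}", samples=rec.samples, genes=rec.genes,
            seed_group=rec.seed_group, t_g=rec.t_g, t_c=rec.t_c,
            n_iterations=rec.n_iterations, converged=rec.converged,
            basin_count=basin,
        ))
    return out


class APISA(BaseEstimator):
    """AP-ISA biclustering estimator.

    Fits on a samples x genes expression matrix (DataFrame or ndarray) and
    exposes the final bicluster set plus full stage provenance.  Parameter
    meanings match :class:`APISAConfig`.

    Attributes
    ----------
    biclusters_ : list of BiclusterRecord
        Final deduplicated biclusters, largest basin first.
    rows_, columns_ : boolean ndarrays, shape (n_biclusters, m) / (n_biclusters, n)
        Scikit-learn bicluster-style indicator arrays.
    ap_result_ : APResult
    seed_groups_ : SeedGroups (selected seeds with thresholds)
    pool_ : FixedPointPool
    provenance_ : dict of per-stage counts
    """

    def __init__(self, k: int = 5, n_seeds: int = 10_000, sparsity: int = 2,
                 total_selected: int = 100, t_range=(1.0, 2.0),
                 t_c: float = 1.0, t_g_overrides=None, direction: str = "up",
                 max_iter: int = 100, min_stable: int = 2,
                 dedup_jaccard: float = 0.8, damping: float = 0.5,
                 ap_max_iter: int = 1000, ap_conv_iter: int = 50,
                 tol_steps: int = 30, random_state: int = 0):
        self.k = k
        self.n_seeds = n_seeds
        self.sparsity = sparsity
        self.total_selected = total_selected
        self.t_range = t_range
        self.t_c = t_c
        self.t_g_overrides = t_g_overrides
        self.direction = direction
        self.max_iter = max_iter
        self.min_stable = min_stable
        self.dedup_jaccard = dedup_jaccard
        self.damping = damping
        self.ap_max_iter = ap_max_iter
        self.ap_conv_iter = ap_conv_iter
        self.tol_steps = tol_steps
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _ids(self, X):
        if isinstance(X, pd.DataFrame):
            return [str(s) for s in X.index], [str(g) for g in X.columns]
        m, n = X.shape
        return [f"S{i:03d}" for i in range(m)], [f"G{j:03d}" for j in range(n)]

    def fit(self, X, y=None):
        """Run the three pipeline stages on an expression matrix."""
        sample_ids, gene_ids = self._ids(X)
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
            np.asarray(X, dtype=float)
        m, n = Xv.shape

        # stage 1: AP clustering tuned to K
        S = similarity_matrix(Xv)
        ap = cluster_with_k(S, self.k, tol_steps=self.tol_steps,
                            rng_seed=self.random_state, damping=self.damping,
                            max_iter=self.ap_max_iter,
                            conv_iter=self.ap_conv_iter)
        if not ap.achieved_k:
            raise APError(
                f"affinity propagation delivered {ap.k_found} clusters, "
                f"not the requested {self.k}"
            )
        log.info("AP: K=%d at preference %.4g (%d probes)", ap.k_found,
                 ap.preference, len(ap.probes))

        # stage 2: seeds
        all_seeds = seeds_mod.generate_seeds(m, self.n_seeds, self.sparsity,
                                             rng_seed=self.random_state + 1)
        groups = seeds_mod.classify_seeds(all_seeds, ap)
        n_retained = groups.n_retained
        selected = seeds_mod.sample_seeds(
            groups, min(self.total_selected, n_retained),
            rng_seed=self.random_state + 2,
        )
        selected = seeds_mod.assign_thresholds(
            selected, t_range=tuple(self.t_range), t_c=self.t_c,
            overrides=self.t_g_overrides,
        )
        log.info("seeds: %d retained, %d discarded, %d selected",
                 n_retained, groups.discarded_count,
                 selected.n_retained)

        # stage 3: per-seed ISA and diversity selection
        P = isa.normalize(Xv)
        pool_index: dict = {}
        pool = FixedPointPool()
        n_vanished = 0
        for gkey in sorted(selected.groups):
            t_g, t_c = selected.group_thresholds[gkey]
            for seed in selected.groups[gkey]:
                res = isa.run_seed(P, seed.as_bool(), t_g, t_c,
                                   max_iter=self.max_iter,
                                   min_stable=self.min_stable,
                                   direction=self.direction)
                if res is None:
                    n_vanished += 1
                    continue
                key = (res.sample_idx.tobytes(), res.gene_idx.tobytes())
                if key in pool_index:
                    pool.basin_counts[pool_index[key]] += 1
                else:
                    pool_index[key] = len(pool.records)
                    rec = BiclusterRecord(
                        id=f"fp{len(pool.records):03d}",
                        samples=frozenset(sample_ids[i]
                                          for i in res.sample_idx),
                        genes=frozenset(gene_ids[j] for j in res.gene_idx),
                        seed_group=int(gkey), t_g=float(t_g), t_c=float(t_c),
                        n_iterations=res.n_iterations, converged=True,
                    )
                    pool.records.append(rec)
                    pool.basin_counts.append(1)
        log.info("ISA: %d fixed points from %d seeds (%d vanished)",
                 len(pool.records), selected.n_retained, n_vanished)

        final = select_diverse(pool, self.dedup_jaccard)
        if not final:
            warnings.warn("no seed converged: empty bicluster set")

        self.sample_ids_ = sample_ids
        self.gene_ids_ = gene_ids
        self.ap_result_ = ap
        self.seed_groups_ = selected
        self.pool_ = pool
        self.biclusters_ = final
        srow = {s: i for i, s in enumerate(sample_ids)}
        gcol = {g: j for j, g in enumerate(gene_ids)}
        self.rows_ = np.zeros((len(final), m), dtype=bool)
        self.columns_ = np.zeros((len(final), n), dtype=bool)
        for bi, rec in enumerate(final):
            self.rows_[bi, [srow[s] for s in rec.samples]] = True
            self.columns_[bi, [gcol[g] for g in rec.genes]] = True
        self.provenance_ = {
            "k_found": ap.k_found,
            "ap_preference": ap.preference,
            "ap_converged": ap.converged,
            "n_seeds": self.n_seeds,
            "n_retained": n_retained,
            "n_discarded": groups.discarded_count,
            "n_selected": selected.n_retained,
            "n_vanished": n_vanished,
            "n_fixed_points": len(pool.records),
            "n_biclusters": len(final),
            "group_thresholds": {int(k): list(v) for k, v in
                                 selected.group_thresholds.items()},
        }
        return self

    def get_biclusters(self) -> BiclusterSet:
        """Final bicluster set with provenance attached."""
        return BiclusterSet(records=list(self.biclusters_),
                            provenance=dict(self.provenance_))


def run_apisa(E, cfg: APISAConfig | None = None) -> BiclusterSet:
    """Functional wrapper: run the full pipeline under one config."""
    cfg = cfg or APISAConfig()
    est = APISA(
        k=cfg.k, n_seeds=cfg.n_seeds, sparsity=cfg.sparsity,
        total_selected=cfg.total_selected, t_range=cfg.t_range, t_c=cfg.t_c,
        t_g_overrides=cfg.t_g_overrides, direction=cfg.direction,
        max_iter=cfg.max_iter, min_stable=cfg.min_stable,
        dedup_jaccard=cfg.dedup_jaccard, damping=cfg.damping,
        ap_max_iter=cfg.ap_max_iter, ap_conv_iter=cfg.ap_conv_iter,
        tol_steps=cfg.tol_steps, random_state=cfg.rng_seed,
    ).fit(E)
    out = est.get_biclusters()
    out.provenance["config"] = cfg.to_dict()
    return out
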