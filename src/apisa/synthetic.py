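"""Planted-bicluster synthetic data: the test substrate for the pipeline.

`planted_expression` emulates the structure the AP-ISA model assumes in a
tumour expression cohort: K latent sample groups of unequal prevalence, each
carrying a block of up-regulated genes over iid Gaussian background noise.
The default prevalences (0.30, 0.15, 0.35, 0.15, 0.05) mirror the unequal
breast-cancer subtype frequencies the method is designed around.

`planted_methylation` produces a companion CpG beta-value matrix in [0, 1]
with per-group, per-region mean levels drawn from Beta distributions, for
exercising region-wise methylation profiling.

The generators are deliberately simple — additive mean-shift blocks,
homoscedastic noise, no batch effects or realistic marginals — so every
recovery statement has an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation import REGION_CATEGORIES
from .records import BiclusterRecord
from .seeds import largest_remainder

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "planted_expression",
    "planted_methylation",
    "recovery_score",
    "best_matches",
    "DEFAULT_PREVALENCES",
]

DEFAULT_PREVALENCES = (0.30, 0.15, 0.35, 0.15, 0.05)


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one planted-bicluster instance.

    ``prevalences`` partition the m samples into latent groups; group i is
    planted with ``genes_per_module`` consecutive genes shifted up by
    ``delta`` noise standard deviations.  Gene blocks are disjoint.
    """

    m: int = 200
    n: int = 500
    prevalences: tuple = DEFAULT_PREVALENCES
    genes_per_module: int = 60
    delta: float = 3.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        if any(p <= 0 for p in self.prevalences):
            raise ValueError("prevalences must be positive")
        if len(self.prevalences) * self.genes_per_module > self.n:
            raise ValueError("disjoint gene blocks exceed n genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted modules and per-sample latent group labels."""

    modules: list  # list of (frozenset sample ids, frozenset gene ids)
    labels: pd.Series  # sample id -> group index
    group_sizes: list = field(default_factory=list)

    def as_records(self) -> list:
        return [
            BiclusterRecord(id=f"truth{i}", samples=s, genes=g)
            for i, (s, g) in enumerate(self.modules)
        ]


def planted_expression(spec: PlantSpec, rng_seed: int = 0):
    """Generate one (expression matrix, ground truth) pair.

    Background entries are iid Normal(0, noise_sd^2); each planted
    (sample, gene) cell receives an additive shift of delta * noise_sd.
    """
    rng = np.random.default_rng(rng_seed)
    m, n = spec.m, spec.n
    sample_ids = [f"S{i:03d}" for i in range(m)]
    gene_ids = [f"G{j:03d}" for j in range(n)]
    X = rng.normal(0.0, spec.noise_sd, size=(m, n))
    sizes = largest_remainder(spec.prevalences, m)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    modules = []
    start = 0
    for gi, sz in enumerate(sizes):
        rows = np.arange(start, start + sz)
        cols = np.arange(gi * spec.genes_per_module,
                         (gi + 1) * spec.genes_per_module)
        X[np.ix_(rows, cols)] += spec.delta * spec.noise_sd
        modules.append((
            frozenset(sample_ids[i] for i in rows),
            frozenset(gene_ids[j] for j in cols),
        ))
        start += sz
    E = pd.DataFrame(X, index=sample_ids, columns=gene_ids)
    truth = GroundTruth(
        modules=modules,
        labels=pd.Series(labels, index=sample_ids, name="group"),
        group_sizes=sizes,
    )
    return E, truth


def planted_methylation(truth: GroundTruth, region_levels,
                        concentration: float = 50.0,
                        cpgs_per_region: int = 50, rng_seed: int = 0):
    """Generate a beta-value matrix with per-group, per-region mean levels.

    ``region_levels`` maps group index -> region category -> mean beta in
    (0, 1) (a nested mapping or a DataFrame with groups as rows).  Each CpG
    beta is drawn from Beta(mu*nu, (1-mu)*nu) with nu = ``concentration``;
    larger nu concentrates values around the requested mean.  CpGs are
    assigned round-robin to the six region categories.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if isinstance(region_levels, pd.DataFrame):
        levels = {g: region_levels.loc[g].to_dict() for g in region_levels.index}
    else:
        levels = {g: dict(v) for g, v in region_levels.items()}
    for g, d in levels.items():
        for r, mu in d.items():
            if r not in REGION_CATEGORIES:
                raise ValueError(f"unknown region category {r!r}")
            if not (0.0 < mu < 1.0):
                raise ValueError(f"mean beta for group {g}, {r} not in (0,1)")
    rng = np.random.default_rng(rng_seed)
    n_cpg = cpgs_per_region * len(REGION_CATEGORIES)
    cpg_ids = [f"cg{i:05d}" for i in range(n_cpg)]
    regions = [REGION_CATEGORIES[i % len(REGION_CATEGORIES)]
               for i in range(n_cpg)]
    annotation = pd.Series(regions, index=cpg_ids, name="region")
    samples = list(truth.labels.index)
    beta = np.empty((n_cpg, len(samples)))
    for j, sid in enumerate(samples):
        grp = int(truth.labels[sid])
        for i, region in enumerate(regions):
            mu = levels[grp][region]
            beta[i, j] = rng.beta(mu * concentration,
                                  (1.0 - mu) * concentration)
    M = pd.DataFrame(beta, index=cpg_ids, columns=samples)
    return M, annotation


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def recovery_score(found: BiclusterRecord, truth_module):
    """(sample Jaccard, gene Jaccard) of a found bicluster vs one module."""
    ts, tg = truth_module
    return _jaccard(found.samples, frozenset(ts)), _jaccard(found.genes,
                                                            frozenset(tg))


def best_matches(records, truth: GroundTruth) -> list:
    """Greedy max-Jaccard assignment of found biclusters to planted modules.

    Pairs are taken in decreasing order of summed sample+gene Jaccard, each
    record and module used at most once.  Returns one entry per module:
    (record or None, sample_jaccard, gene_jaccard).
    """
    records = list(records)
    pairs = []
    for ri, rec in enumerate(records):
        for mi, mod in enumerate(truth.modules):
            sj, gj = recovery_score(rec, mod)
            pairs.append((sj + gj, ri, mi, sj, gj))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_r: set = set()
    out: dict = {}
    for _, ri, mi, sj, gj in pairs:
        if ri in used_r or mi in out:
            continue
        used_r.add(ri)
        out[mi] = (records[ri], sj, gj)
    return [out.get(mi, (None, 0.0, 0.0)) for mi in range(len(truth.modules))]
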