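"""Bicluster containers shared across the package.

A bicluster is a (sample set, gene set) pair whose sub-matrix shows coherent,
here elevated, expression.  Samples and genes may belong to several
biclusters; overlap is a feature of the model, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class BiclusterRecord:
    """One bicluster with its provenance.

    Parameters
    ----------
    id : str
        Stable identifier, unique within a set.
    samples, genes : frozenset of str
        Member identifiers; both must be non-empty.
    seed_group : int or None
        Index of the seed group (affinity-propagation cluster) whose seed
        converged to this fixed point, when known.
    t_g, t_c : float or None
        Gene- and sample-axis thresholds (score standard-deviation units)
        under which the fixed point was found.
    n_iterations : int or None
        Iterations the signature update took to stabilise.
    converged : bool
        Whether the iteration reached exact support stability.
    basin_count : int
        Number of seeds that converged to this fixed point.
    """

    id: str
    samples: frozenset
    genes: frozenset
    seed_group: int | None = None
    t_g: float | None = None
    t_c: float | None = None
    n_iterations: int | None = None
    converged: bool = True
    basin_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", frozenset(self.samples))
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.samples:
            raise ValueError(f"bicluster {self.id!r}: empty sample set")
        if not self.genes:
            raise ValueError(f"bicluster {self.id!r}: empty gene set")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def entry_set(self) -> set:
        """All (sample, gene) matrix entries covered by this bicluster."""
        return {(s, g) for s in self.samples for g in self.genes}

    def axis_union(self) -> frozenset:
        """Tagged union of sample and gene entries, for overlap comparison."""
        return frozenset(("s", s) for s in self.samples) | frozenset(
            ("g", g) for g in self.genes
        )


@dataclass
class BiclusterSet:
    """An ordered collection of biclusters plus run provenance."""

    records: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiclusterRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list:
        return [r.id for r in self.records]


def combined_jaccard(a: BiclusterRecord, b: BiclusterRecord) -> float:
    """Jaccard index on the tagged union of sample and gene memberships."""
    ua, ub = a.axis_union(), b.axis_union()
    inter = len(ua & ub)
    union = len(ua | ub)
    return inter / union if union else 0.0
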