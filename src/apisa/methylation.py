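"""Region-wise DNA-methylation profiling.

Methylation of a CpG site is summarised by its beta value (methylated /
total signal, in [0, 1]).  CpGs are annotated to one of six genomic region
categories relative to a gene — TSS200, TSS1500, 5'UTR, 1st exon, gene body
and 3'UTR; the first four make up the promoter region.  The profile of a
sample is its mean beta per category, optionally restricted to a bicluster's
sample set, which is how promoter hypo-/hypermethylation contrasts between
expression subtypes are read out.

Missing beta values are excluded pairwise from the means; a category with no
contributing CpG is reported missing, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["REGION_CATEGORIES", "RegionProfile", "region_mean_beta",
           "profile_biclusters"]

REGION_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "GeneBody",
                     "3'UTR")


@dataclass
class RegionProfile:
    """Per-sample mean beta per region, with contributing-CpG counts."""

    means: pd.DataFrame   # samples x regions, NaN where no CpG contributes
    counts: pd.DataFrame  # samples x regions, non-missing CpGs per cell


def region_mean_beta(M: pd.DataFrame, annotation: pd.Series,
                     samples=None) -> RegionProfile:
    """Mean beta per region category for each (requested) sample.

    Parameters
    ----------
    M : DataFrame, CpG rows x sample columns, values in [0, 1] or NaN.
    annotation : Series mapping cpg_id -> region category; may cover only a
        subset of M's CpGs (unannotated CpGs are ignored).
    samples : optional iterable of sample ids to restrict to.
    """
    bad = set(annotation.unique()) - set(REGION_CATEGORIES)
    if bad:
        raise ValueError(f"unknown region categories: {sorted(bad)}")
    if samples is not None:
        samples = list(samples)
        missing = [s for s in samples if s not in M.columns]
        if missing:
            raise KeyError(f"samples not in methylation matrix: {missing}")
        M = M[samples]
    ann = annotation[annotation.index.intersection(M.index)]
    sub = M.loc[ann.index]
    grouped = sub.groupby(ann, observed=True)
    means = grouped.mean().T  # pandas mean skips NaN (pairwise deletion)
    counts = grouped.count().T
    means = means.reindex(columns=list(REGION_CATEGORIES))
    counts = counts.reindex(columns=list(REGION_CATEGORIES), fill_value=0)
    return RegionProfile(means=means, counts=counts.astype(int))


def profile_biclusters(M: pd.DataFrame, annotation: pd.Series,
                       records) -> dict:
    """Region profile restricted to each bicluster's sample set.

    Samples absent from the methylation matrix are logged and skipped; a
    bicluster with no resolvable sample is skipped entirely with a warning.
    Returns a dict keyed by bicluster id.
    """
    out = {}
    for rec in records:
        present = [s for s in sorted(rec.samples) if s in M.columns]
        dropped = len(rec.samples) - len(present)
        if dropped:
            log.warning("bicluster %s: %d samples missing from methylation "
                        "matrix", rec.id, dropped)
        if not present:
            log.warning("bicluster %s skipped: no samples resolvable", rec.id)
            continue
        out[rec.id] = region_mean_beta(M, annotation, samples=present)
    return out
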