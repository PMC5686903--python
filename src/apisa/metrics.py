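"""Evaluation statistics for bicluster sets.

The centrepiece is the effective number of biclusters F: an
overlap-corrected count in which every matrix entry x contributes 1/N(x) to
each of the N(x) biclusters containing it,

    F(U_1, ..., U_K) = sum_k (1/|U_k|) * sum_{x in U_k} 1/N(x),

where U_k is the set of (sample, gene) entries of bicluster k.  F is bounded
by 1 <= F <= K, equals K exactly when the biclusters are pairwise disjoint,
and equals r whenever the set splits into r non-overlapping groups of
identical biclusters — so F/K measures how much non-redundant structure a
method reports.

Also here: per-bicluster size summaries and capture tables against reference
sample labels (e.g. PAM50 subtype calls), which is how a bicluster is
matched to a known subtype.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

__all__ = ["effective_number", "size_summary", "size_stats", "capture_table",
           "match_subtypes"]


def effective_number(records) -> float:
    """Overlap-corrected effective number of biclusters F."""
    records = list(records)
    if not records:
        raise ValueError("effective_number of an empty bicluster list")
    entry_sets = [rec.entry_set() for rec in records]
    if any(not es for es in entry_sets):
        raise ValueError("bicluster with empty entry set")
    n_containing: Counter = Counter()
    for es in entry_sets:
        n_containing.update(es)
    total = 0.0
    for es in entry_sets:
        total += sum(1.0 / n_containing[x] for x in es) / len(es)
    return total


def size_summary(records) -> pd.DataFrame:
    """Per-bicluster (n_samples, n_genes) table, indexed by id."""
    records = list(records)
    return pd.DataFrame(
        {
            "n_samples": [r.n_samples for r in records],
            "n_genes": [r.n_genes for r in records],
        },
        index=pd.Index([r.id for r in records], name="id"),
    )


def size_stats(records) -> pd.DataFrame:
    """Min / median / max per axis over a bicluster set."""
    df = size_summary(records)
    if df.empty:
        return pd.DataFrame(columns=["min", "median", "max"])
    return pd.DataFrame(
        {
            "min": df.min(),
            "median": df.median(),
            "max": df.max(),
        }
    )


def _label_counts(rec, labels: pd.Series) -> Counter:
    c: Counter = Counter()
    for s in rec.samples:
        if s in labels.index and not pd.isna(labels[s]):
            c[str(labels[s])] += 1
        else:
            c["NA"] += 1
    return c


def capture_table(records, labels: pd.Series) -> pd.DataFrame:
    """Sample counts per (bicluster, reference label).

    Rows are biclusters, columns the label categories plus ``total``; a
    sample in several biclusters is counted in each of their rows.  Samples
    without a label are counted under ``NA``.
    """
    records = list(records)
    cats = sorted({str(v) for v in labels.dropna().unique()})
    rows = {}
    any_na = False
    for rec in records:
        c = _label_counts(rec, labels)
        any_na = any_na or c["NA"] > 0
        rows[rec.id] = c
    cols = cats + (["NA"] if any_na else [])
    table = pd.DataFrame(
        [[rows[rid].get(col, 0) for col in cols] for rid in rows],
        index=pd.Index(list(rows), name="id"),
        columns=cols,
        dtype=int,
    )
    table["total"] = table.sum(axis=1)
    return table


def match_subtypes(records, labels: pd.Series, min_fraction: float = 0.5) -> dict:
    """Assign each bicluster to at most one reference label.

    A bicluster matches its most frequent label iff that label accounts for
    at least ``min_fraction`` of the bicluster's samples.  Returns a mapping
    label -> list of matching bicluster ids; labels never reached by any
    bicluster map to an empty list ("not captured").
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    cats = sorted({str(v) for v in labels.dropna().unique()})
    out: dict = {cat: [] for cat in cats}
    for rec in records:
        c = _label_counts(rec, labels)
        c.pop("NA", None)
        if not c:
            continue
        best, count = max(c.items(), key=lambda kv: (kv[1], kv[0]))
        if count / rec.n_samples >= min_fraction:
            out[best].append(rec.id)
    return out
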