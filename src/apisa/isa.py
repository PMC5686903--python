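"""Iterative signature algorithm (ISA) fixed-point engine.

The ISA searches an expression matrix E (samples x genes) for transcription
modules: pairs of a sample set and a gene set that reinforce each other under
an alternating projection.  Starting from a sparse binary sample vector c0,
gene scores are computed as the mean row-normalised expression over the
selected samples and thresholded at ``t_g`` standard deviations; the selected
genes then score the samples on the column-normalised matrix, thresholded at
``t_c``; the loop repeats until the two support sets stop changing.

All membership vectors are binary.  Scores are averaged over the selected
rows/columns so that thresholds remain comparable across seed sizes.
Standard deviations use the sample (n-1) convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedPair",
    "normalize",
    "threshold_scores",
    "isa_step",
    "run_seed",
    "ISAResult",
]


@dataclass(frozen=True)
class NormalizedPair:
    """Row- and column-normalised copies of one expression matrix.

    ``e_c`` has every sample row at mean 0, sd 1 (used to score genes);
    ``e_g`` has every gene column at mean 0, sd 1 (used to score samples).
    """

    e_c: np.ndarray
    e_g: np.ndarray

    @property
    def shape(self):
        return self.e_c.shape


@dataclass(frozen=True)
class ISAResult:
    """Converged fixed point of one seed run (indices into the matrix)."""

    sample_idx: np.ndarray
    gene_idx: np.ndarray
    n_iterations: int
    converged: bool


def normalize(E) -> NormalizedPair:
    """Build the row-normalised and column-normalised matrices.

    Parameters
    ----------
    E : ndarray or DataFrame of shape (m_samples, n_genes)

    Raises
    ------
    ValueError
        If any row or column is constant; the offenders are named so the
        caller can drop them and retry.
    """
    ids_r = ids_c = None
    if hasattr(E, "to_numpy"):
        ids_r = list(E.index)
        ids_c = list(E.columns)
        X = E.to_numpy(dtype=float)
    else:
        X = np.asarray(E, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("expression matrix must be 2-D with m >= 2, n >= 2")
    row_sd = X.std(axis=1, ddof=1)
    col_sd = X.std(axis=0, ddof=1)
    bad_rows = np.flatnonzero(row_sd == 0)
    bad_cols = np.flatnonzero(col_sd == 0)
    if bad_rows.size or bad_cols.size:
        rn = [ids_r[i] if ids_r else int(i) for i in bad_rows]
        cn = [ids_c[j] if ids_c else int(j) for j in bad_cols]
        raise ValueError(
            f"constant rows/columns cannot be normalised: rows={rn} columns={cn}"
        )
    e_c = (X - X.mean(axis=1, keepdims=True)) / row_sd[:, None]
    e_g = (X - X.mean(axis=0, keepdims=True)) / col_sd[None, :]
    return NormalizedPair(e_c=e_c, e_g=e_g)


def threshold_scores(scores, t: float, direction: str = "up") -> np.ndarray:
    """Binarise a score vector at ``t`` standard deviations above its mean.

    The vector is standardised (z = (score - mean) / sd, sample sd) and an
    index is kept iff z > t (``direction='up'``) or \\|z\\| > t
    (``direction='updown'``).  A constant vector yields an all-zero result
    with a warning rather than an exception.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("scores must be a 1-D vector of length >= 2")
    if direction not in ("up", "updown"):
        raise ValueError(f"unknown direction {direction!r}")
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("constant score vector: nothing passes the threshold")
        return np.zeros(s.size, dtype=bool)
    z = (s - s.mean()) / sd
    return (z > t) if direction == "up" else (np.abs(z) > t)


def isa_step(P: NormalizedPair, c, t_g: float, t_c: float,
             direction: str = "up"):
    """One alternating update: samples -> genes -> samples.

    Gene scores are the mean of the row-normalised matrix over the selected
    samples; sample scores the mean of the column-normalised matrix over the
    selected genes.  Returns ``(g, c_next)`` as boolean vectors.  If the gene
    set empties the module has vanished and ``(g, None)`` is returned.

    Raises
    ------
    ValueError
        If ``c`` has no selected sample.
    """
    c = np.asarray(c, dtype=bool)
    if not c.any():
        raise ValueError("empty sample vector")
    gene_scores = P.e_c[c].mean(axis=0)
    g = threshold_scores(gene_scores, t_g, direction)
    if not g.any():
        return g, None
    sample_scores = P.e_g[:, g].mean(axis=1)
    c_next = threshold_scores(sample_scores, t_c, direction)
    return g, c_next


def run_seed(P: NormalizedPair, seed, t_g: float, t_c: float,
             max_iter: int = 100, min_stable: int = 2,
             direction: str = "up") -> ISAResult | None:
    """Iterate one seed to a transcription module, or report its loss.

    Convergence is exact support equality of both the gene and the sample
    set over ``min_stable`` consecutive iterations.  Returns ``None`` when
    the module vanishes (either axis empties) or ``max_iter`` passes without
    stabilising.
    """
    c = np.asarray(seed, dtype=bool)
    if not c.any():
        raise ValueError("empty seed")
    if max_iter < min_stable or min_stable < 1:
        raise ValueError("require max_iter >= min_stable >= 1")
    prev_state = None
    stable = 0
    for it in range(1, max_iter + 1):
        g, c_next = isa_step(P, c, t_g, t_c, direction)
        if c_next is None or not c_next.any():
            return None
        state = (g.tobytes(), c_next.tobytes())
        if state == prev_state:
            stable += 1
            if stable >= min_stable:
                return ISAResult(
                    sample_idx=np.flatnonzero(c_next),
                    gene_idx=np.flatnonzero(g),
                    n_iterations=it,
                    converged=True,
                )
        else:
            stable = 0
        prev_state = state
        c = c_next
    return None
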