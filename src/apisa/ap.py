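"""Affinity propagation over samples, with a search for a requested K.

Affinity propagation (AP) clusters by exchanging responsibility and
availability messages over a pairwise similarity matrix; each cluster is
represented by an exemplar data point.  AP has no native cluster-count
parameter — the number of clusters emerges from the shared "preference"
placed on the similarity diagonal — so `cluster_with_k` wraps the message
passing in a bracketed bisection on the preference until the requested K is
reached.

The default similarity is the negative squared Euclidean distance between
sample rows, the classic AP choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = [
    "similarity_matrix",
    "affinity_propagation",
    "cluster_with_k",
    "APResult",
    "APClusterK",
]

# scale of the seeded tie-breaking noise added to similarities; degenerate
# exactly-symmetric inputs otherwise oscillate forever
_NOISE_SCALE = 1e-12


@dataclass
class APResult:
    """Outcome of one affinity-propagation run.

    ``labels`` holds a 0-based cluster index per sample; each cluster has
    exactly one exemplar, and an exemplar's own label points to itself.
    """

    labels: np.ndarray
    exemplars: np.ndarray
    preference: float
    n_iterations: int
    converged: bool
    k_found: int
    achieved_k: bool = True
    probes: list = field(default_factory=list)

    def net_similarity(self, S: np.ndarray) -> float:
        """AP objective: preferences of exemplars plus member similarities."""
        total = self.preference * len(self.exemplars)
        for i, lab in enumerate(self.labels):
            k = self.exemplars[lab]
            if i != k:
                total += S[i, k]
        return float(total)


def similarity_matrix(E) -> np.ndarray:
    """Negative squared Euclidean similarities between sample rows.

    The diagonal is left at 0; it is overwritten by the preference when the
    message passing runs.
    """
    X = E.to_numpy(dtype=float) if hasattr(E, "to_numpy") else np.asarray(E, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("expected a 2-D samples x genes matrix")
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    S = -squareform(pdist(X, metric="sqeuclidean"))
    return S


# problem size up to which the exemplar local search restarts from every
# singleton as well as from the message-passing solution (cost O(m^3))
_MULTISTART_LIMIT = 40


def _exemplar_value(S_assign, preference, exemplars):
    """Net similarity of an exemplar set under the AP objective."""
    ex = list(exemplars)
    best = S_assign[:, ex].max(axis=1)
    mask = np.ones(S_assign.shape[0], dtype=bool)
    mask[ex] = False
    return preference * len(ex) + best[mask].sum()


def _local_search(S_assign, preference, start, max_sweeps=50):
    """Best-improvement add/drop/swap search on the exemplar set.

    Message passing can converge to a slightly sub-optimal exemplar
    configuration; this greedy polish on the net-similarity objective
    (exemplars pay the preference, the rest attach to their best exemplar)
    removes such gaps.  The neighbourhood is one added, removed or swapped
    exemplar per move.
    """
    m = S_assign.shape[0]
    X = set(int(x) for x in start)
    cur = _exemplar_value(S_assign, preference, X)
    for _ in range(max_sweeps):
        candidates = []
        outside = [j for j in range(m) if j not in X]
        for j in outside:
            candidates.append(X | {j})
        if len(X) > 1:
            for x in X:
                candidates.append(X - {x})
        for x in list(X):
            for j in outside:
                candidates.append((X - {x}) | {j})
        values = [_exemplar_value(S_assign, preference, c)
                  for c in candidates]
        k_best = int(np.argmax(values))
        if values[k_best] <= cur + 1e-12:
            break
        X, cur = candidates[k_best], values[k_best]
    return X, cur


def affinity_propagation(S, preference: float, damping: float = 0.5,
                         max_iter: int = 1000, conv_iter: int = 50,
                         rng_seed: int = 0) -> APResult:
    """Standard responsibility/availability message passing.

    Converged means the exemplar set was unchanged for ``conv_iter``
    consecutive sweeps; running out of ``max_iter`` sweeps returns a result
    flagged ``converged=False``, never an exception.  The converged exemplar
    set is finished with a local search on the net-similarity objective
    (see :func:`_local_search`); on small problems the search additionally
    restarts from every singleton configuration.
    """
    S = np.array(S, dtype=float)
    m = S.shape[0]
    if S.shape != (m, m):
        raise ValueError("similarity matrix must be square")
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must be in [0.5, 1)")
    if not (max_iter >= conv_iter >= 1):
        raise ValueError("require max_iter >= conv_iter >= 1")
    if m == 1:
        return APResult(np.zeros(1, int), np.array([0]), preference, 0, True, 1)

    rng = np.random.default_rng(rng_seed)
    np.fill_diagonal(S, preference)
    S = S + _NOISE_SCALE * rng.standard_normal(S.shape) * (
        np.abs(S).max() + 1.0
    )

    R = np.zeros((m, m))
    A = np.zeros((m, m))
    idx = np.arange(m)
    last_exemplars = None
    stable = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first_k = AS.argmax(axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        Rp[idx, idx] = R[idx, idx]
        Anew = Rp.sum(axis=0)[None, :] - Rp
        diag = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0.0)
        Anew[idx, idx] = diag
        A = damping * A + (1.0 - damping) * Anew

        exemplars = frozenset(np.flatnonzero((A + R).diagonal() > 0))
        if exemplars and exemplars == last_exemplars:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    ex = np.flatnonzero((A + R).diagonal() > 0)
    if ex.size == 0:
        ex = np.array([int((A + R).diagonal().argmax())])
        converged = False
    S_assign = S.copy()
    np.fill_diagonal(S_assign, -np.inf)  # points never attach to themselves
    starts = [set(int(x) for x in ex)]
    if m <= _MULTISTART_LIMIT:
        starts += [{i} for i in range(m)]
    best_set, best_val = None, -np.inf
    for start in starts:
        cand, v = _local_search(S_assign, preference, start)
        if v > best_val:
            best_set, best_val = cand, v
    ex = np.array(sorted(best_set))
    labels = S_assign[:, ex].argmax(axis=1)
    labels[ex] = np.arange(ex.size)
    return APResult(
        labels=labels,
        exemplars=ex,
        preference=float(preference),
        n_iterations=n_iter,
        converged=converged,
        k_found=int(ex.size),
    )


def cluster_with_k(S, K: int, tol_steps: int = 30, rng_seed: int = 0,
                   damping: float = 0.5, max_iter: int = 1000,
                   conv_iter: int = 50) -> APResult:
    """Bisection on a shared preference until AP yields K clusters.

    The number of clusters is non-decreasing in the preference, so a
    bracketed bisection starting from [min, max] of the off-diagonal
    similarities homes in on K.  Small K often needs a preference well below
    the minimum similarity, so the bracket is expanded geometrically in
    either direction when K lies outside what it can deliver.  If
    ``tol_steps`` probes are exhausted the result with the closest cluster
    count is returned, flagged ``achieved_k=False``.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    if not (1 <= K <= m):
        raise ValueError(f"K={K} outside [1, {m}]")
    if m == 1:
        return APResult(np.zeros(1, int), np.array([0]), 0.0, 0, True, 1)
    off = S[~np.eye(m, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    if lo == hi:
        lo -= 1.0
    probes: list = []
    best: APResult | None = None

    def probe(p: float) -> APResult:
        res = affinity_propagation(S, p, damping, max_iter, conv_iter, rng_seed)
        probes.append((p, res.k_found, res.converged))
        nonlocal best
        if best is None or abs(res.k_found - K) < abs(best.k_found - K) or (
            abs(res.k_found - K) == abs(best.k_found - K)
            and res.converged
            and not best.converged
        ):
            best = res
        return res

    steps = 0
    res_hi = probe(hi)
    steps += 1
    if res_hi.k_found == K:
        res_hi.probes = probes
        return res_hi
    # expand upward when even the max similarity under-delivers
    while res_hi.k_found < K and steps < tol_steps:
        width = hi - lo
        lo, hi = hi, hi + max(width, 1.0)
        res_hi = probe(hi)
        steps += 1
        if res_hi.k_found == K:
            res_hi.probes = probes
            return res_hi
    if steps < tol_steps:
        res_lo = probe(lo)
        steps += 1
        if res_lo.k_found == K:
            res_lo.probes = probes
            return res_lo
        # expand downward: few clusters need preferences far below min(S)
        while res_lo.k_found > K and steps < tol_steps:
            width = hi - lo
            hi, lo = lo, lo - max(width, 1.0)
            res_lo = probe(lo)
            steps += 1
            if res_lo.k_found == K:
                res_lo.probes = probes
                return res_lo
    while steps < tol_steps:
        mid = 0.5 * (lo + hi)
        res = probe(mid)
        steps += 1
        if res.k_found == K:
            res.probes = probes
            return res
        if res.k_found < K:
            lo = mid
        else:
            hi = mid
    assert best is not None
    log.warning("K=%d not attained in %d probes; closest K_found=%d",
                K, tol_steps, best.k_found)
    best.achieved_k = best.k_found == K
    best.probes = probes
    return best


class APClusterK(BaseEstimator, ClusterMixin):
    """Affinity-propagation clustering tuned to a requested cluster count.

    Scikit-learn style estimator over a samples x genes matrix: similarities
    are negative squared Euclidean distances, and the AP preference is
    bisected until ``k`` clusters emerge.

    Parameters
    ----------
    k : int
        Requested number of clusters.
    damping : float, default 0.5
        Message damping factor in [0.5, 1).
    max_iter, conv_iter : int
        Sweep budget and required exemplar-stability run for convergence.
    tol_steps : int, default 30
        Maximum preference probes in the bisection.
    random_state : int, default 0
        Seed for the tie-breaking noise.

    Attributes
    ----------
    labels_ : ndarray of shape (m,)
        Cluster index per sample.
    exemplar_indices_ : ndarray
        Row indices of the exemplars.
    preference_ : float
        Preference that produced the returned clustering.
    k_found_ : int
    achieved_k_ : bool
    result_ : APResult
    """

    def __init__(self, k: int = 5, damping: float = 0.5, max_iter: int = 1000,
                 conv_iter: int = 50, tol_steps: int = 30,
                 random_state: int = 0):
        self.k = k
        self.damping = damping
        self.max_iter = max_iter
        self.conv_iter = conv_iter
        self.tol_steps = tol_steps
        self.random_state = random_state

    def fit(self, X, y=None):
        S = similarity_matrix(X)
        res = cluster_with_k(
            S, self.k, tol_steps=self.tol_steps, rng_seed=self.random_state,
            damping=self.damping, max_iter=self.max_iter,
            conv_iter=self.conv_iter,
        )
        self.result_ = res
        self.labels_ = res.labels
        self.exemplar_indices_ = res.exemplars
        self.preference_ = res.preference
        self.k_found_ = res.k_found
        self.achieved_k_ = res.achieved_k
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        check_is_fitted(self, "labels_")
        return self.labels_
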