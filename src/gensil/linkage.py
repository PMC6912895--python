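"""Agglomerative hierarchical clustering via Lance-Williams updates.

Stored-matrix agglomeration: starting from the object dissimilarity
matrix, the closest pair of clusters is merged repeatedly and the
distance from the new cluster ``m = i ∪ j`` to every other cluster
``h`` is updated by the Lance-Williams recurrence

    d(m, h) = a_i d(i, h) + a_j d(j, h) + beta d(i, j)
              + gamma |d(i, h) - d(j, h)|

with coefficients

    single        a_i = a_j = 1/2,              beta = 0,  gamma = -1/2
    complete      a_i = a_j = 1/2,              beta = 0,  gamma = +1/2
    average       a_i = n_i/(n_i+n_j), ...      beta = 0,  gamma = 0
    flexible_beta a_i = a_j = (1 - beta)/2,     gamma = 0  (beta given,
                  conventionally -0.25; beta = 0 is McQuitty/WPGMA)

Ties in the minimal dissimilarity break on the lexicographically
smallest pair of node ids, so results are deterministic.  The O(n^3)
stored-matrix scheme is deliberate: it follows the recurrence verbatim
and is comfortably fast for the n <= 1000 problems this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["METHODS", "MergeTree", "agglomerate", "cut_tree"]

METHODS = ("single", "average", "complete", "flexible_beta")


@dataclass(frozen=True)
class MergeTree:
    """Merge sequence of an agglomerative clustering of ``n`` objects.

    ``merges`` has one row per merge: ``(left, right, height)`` where
    left/right are node ids (0..n-1 for leaves; the merge at row ``t``
    creates node ``n + t``) and height is the dissimilarity at which
    the pair merged.
    """

    n: int
    merges: np.ndarray  # (n-1, 3) float; ids are integral
    method: str
    beta: float | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_linkage_matrix(self) -> np.ndarray:
        """Conventional (n-1) x 4 linkage layout (with cluster sizes)."""
        Z = np.zeros((self.n - 1, 4))
        size = {i: 1 for i in range(self.n)}
        for t, (l, r, h) in enumerate(self.merges):
            l, r = int(l), int(r)
            size[self.n + t] = size[l] + size[r]
            Z[t] = (l, r, h, size[self.n + t])
        return Z

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "left": self.merges[:, 0].astype(int),
                "right": self.merges[:, 1].astype(int),
                "height": self.merges[:, 2],
                "new_node": np.arange(self.n, 2 * self.n - 1),
            }
        )


def _coefficients(method: str, beta: float, ni: float, nj: float):
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "average":
        tot = ni + nj
        return ni / tot, nj / tot, 0.0, 0.0
    if method == "flexible_beta":
        a = (1.0 - beta) / 2.0
        return a, a, beta, 0.0
    raise ValueError(f"unknown linkage method {method!r}; choose from {METHODS}")


def agglomerate(D, method: str = "average", beta: float = -0.25) -> MergeTree:
    """Cluster a dissimilarity matrix agglomeratively.

    Parameters
    ----------
    D
        n x n symmetric dissimilarity matrix (n >= 2).
    method
        ``"single"``, ``"average"`` (UPGMA), ``"complete"`` or
        ``"flexible_beta"``.
    beta
        Lance-Williams beta, used only by ``flexible_beta``; must lie
        in (-1, 1).  Default -0.25, the conventional space-conserving
        choice.
    """
    from .silhouette import validate_dissimilarity

    D = validate_dissimilarity(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("agglomeration requires at least 2 objects")
    if method == "flexible_beta" and not (-1.0 < beta < 1.0):
        raise ValueError("beta must lie in (-1, 1)")
    _coefficients(method, beta, 1, 1)  # validate the method name early

    work = D.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    ids = np.arange(n)          # active node ids, ascending
    sizes = np.ones(n)
    merges = np.empty((n - 1, 3))

    for t in range(n - 1):
        m = ids.size
        # Row-major argmin over the symmetric matrix (inf diagonal)
        # lands on the i < j copy first, so ties break on the smallest
        # (i, j) pair; ids stay sorted ascending, so position order is
        # node-id order.
        best = int(np.argmin(work))
        i, j = divmod(best, m)
        dij = work[i, j]

        merges[t] = (ids[i], ids[j], dij)
        keep = np.ones(m, dtype=bool)
        keep[[i, j]] = False

        ai, aj, b, g = _coefficients(method, beta, sizes[i], sizes[j])
        di, dj = work[i, keep], work[j, keep]
        new_row = ai * di + aj * dj + b * dij
        if g != 0.0:
            new_row = new_row + g * np.abs(di - dj)
        work = work[np.ix_(keep, keep)]
        work = np.pad(work, ((0, 1), (0, 1)))
        work[-1, :-1] = new_row
        work[:-1, -1] = new_row
        work[-1, -1] = np.inf
        sizes = np.append(sizes[keep], sizes[i] + sizes[j])
        ids = np.append(ids[keep], n + t)

    return MergeTree(
        n=n, merges=merges, method=method,
        beta=beta if method == "flexible_beta" else None,
    )


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Partition into ``k`` clusters by undoing the last ``k - 1`` merges.

    Labels are consecutive integers starting at 0, assigned by order of
    first member appearance, so the output is deterministic and
    comparable across cuts.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # union the first n - k merges under their created node id
    for t in range(n - k):
        l, r, _ = tree.merges[t]
        new = n + t
        parent[find(int(l))] = new
        parent[find(int(r))] = new

    roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        labels[i] = seen.setdefault(r, len(seen))
    return labels
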