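"""Generalized silhouette widths from a dissimilarity matrix and a partition.

For a focal object ``i`` in cluster ``A``, the within-cluster distance
``a(i)`` is the power mean ``M_p`` of the distances from ``i`` to the
other members of ``A``; for every other cluster ``C``, ``c(i, C)`` is
the ``M_p`` of the distances from ``i`` to all members of ``C``, and
``b(i) = min_C c(i, C)``.  The silhouette width is

    s(i) = (b(i) - a(i)) / max(a(i), b(i))        in [-1, 1].

``p = 1`` recovers Rousseeuw's classic silhouette; ``p = -inf`` scores
connectedness (nearest neighbours only) and ``p = +inf`` the strictest
compactness (farthest members).  Objects alone in their cluster take
the conventional value s = 0.

Sample-level summaries are the mean silhouette width (MSW, arithmetic
mean of s over objects — the exponent p applies only inside a and b)
and the misclassification rate (MR, the proportion of objects with
strictly negative s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .powermean import parse_exponent, rowwise_generalized_mean

__all__ = [
    "DEFAULT_P_GRID",
    "ValiditySummary",
    "validate_dissimilarity",
    "silhouette_widths",
    "validity_summary",
    "silhouette_profile",
    "summaries_frame",
]

#: Default exponent grid: every classical special case of the power
#: mean (min, harmonic, geometric, arithmetic, quadratic, max) plus
#: symmetric integer padding around zero.
DEFAULT_P_GRID: tuple[float, ...] = (
    -np.inf, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, np.inf,
)


def validate_dissimilarity(D, *, atol: float = 1e-8) -> np.ndarray:
    """Check and return a square symmetric nonnegative distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"dissimilarity matrix must be square, got {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity matrix must be finite")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be nonnegative")
    if not np.allclose(D, D.T, atol=atol, rtol=0):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diagonal(D)) > atol):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return D


@dataclass(frozen=True)
class ValiditySummary:
    """Sample-level validity of one partition at one exponent p."""

    p: float
    n: int
    msw: float                       # arithmetic mean of s(i)
    mr: float                        # share of objects with s(i) < 0
    cluster_msw: pd.Series = field(repr=False)  # mean s(i) per cluster

    def as_dict(self) -> dict:
        return {"p": self.p, "n": self.n, "msw": self.msw, "mr": self.mr}


def silhouette_widths(D, labels, p: float = 1.0) -> pd.DataFrame:
    """Per-object generalized silhouette table at exponent ``p``.

    Parameters
    ----------
    D
        n x n symmetric dissimilarity matrix with zero diagonal.
    labels
        Length-n cluster label per object (ints or strings); at least
        two distinct clusters.
    p
        Power-mean exponent for the within/between averages
        (``"-inf"``/``"inf"`` tokens accepted).

    Returns
    -------
    pandas.DataFrame
        Columns ``object_id, cluster, neighbor, a, b, s`` indexed by
        object position; ``p`` is stored in ``.attrs["p"]``.  For a
        singleton cluster a is recorded as 0 and s = 0; ties in the
        nearest other cluster resolve to the smallest label in sorted
        order.
    """
    D = validate_dissimilarity(D)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape != (n,):
        raise ValueError(
            f"labels length {labels.shape} does not match matrix size {n}"
        )
    p = parse_exponent(p)

    uniq, code = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")

    # cmat[i, j] = M_p of distances from object i to cluster j, with the
    # focal object's own self-distance excluded from its own column.
    cmat = np.empty((n, k))
    sizes = np.bincount(code, minlength=k)
    for j in range(k):
        members = np.flatnonzero(code == j)
        sub = D[:, members].copy()
        sub[members, np.arange(members.size)] = np.nan  # drop d(i, i)
        cmat[:, j] = rowwise_generalized_mean(sub, p)

    a = cmat[np.arange(n), code]
    between = cmat.copy()
    between[np.arange(n), code] = np.inf
    neighbor_code = np.argmin(between, axis=1)  # ties -> smallest label
    b = between[np.arange(n), neighbor_code]

    singleton = sizes[code] == 1
    a = np.where(singleton, 0.0, a)

    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.where(singleton, 0.0, s)
    s = np.clip(s, -1.0, 1.0)

    tab = pd.DataFrame(
        {
            "object_id": np.arange(n),
            "cluster": uniq[code],
            "neighbor": uniq[neighbor_code],
            "a": a,
            "b": b,
            "s": s,
        }
    )
    tab.attrs["p"] = p
    return tab


def validity_summary(tab: pd.DataFrame) -> ValiditySummary:
    """MSW, MR and per-cluster mean silhouette for one silhouette table."""
    if len(tab) == 0:
        raise ValueError("empty silhouette table")
    s = tab["s"].to_numpy()
    return ValiditySummary(
        p=float(tab.attrs.get("p", np.nan)),
        n=len(tab),
        msw=float(s.mean()),
        mr=float(np.mean(s < 0)),
        cluster_msw=tab.groupby("cluster", sort=True)["s"].mean(),
    )


def silhouette_profile(D, labels, p_grid=DEFAULT_P_GRID) -> list[ValiditySummary]:
    """Validity summaries for one fixed partition across a grid of p."""
    p_grid = [parse_exponent(p) for p in p_grid]
    if not p_grid:
        raise ValueError("p_grid must be nonempty")
    return [validity_summary(silhouette_widths(D, labels, p)) for p in p_grid]


def summaries_frame(summaries) -> pd.DataFrame:
    """Stack ValiditySummary records into a (p, n, msw, mr) frame."""
    return pd.DataFrame([s.as_dict() for s in summaries])
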