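"""Seeded 2-D point-pattern archetypes for benchmarking cluster validity.

Each archetype is a 100-point, two-cluster planar configuration chosen
to isolate one combination of the three clustering criteria —
separation, compactness and connectedness:

``random_split``
    uniform square split by the vertical bisector (no real structure).
``transitional``
    two Gaussian blobs joined by a sparse bridge of intermediate
    points, labelled by the nearest blob centre.
``distinct``
    two widely separated compact blobs.
``offset_pairs_same`` / ``offset_pairs_diff``
    two overlapping blobs in which every point has a duplicate at a
    tiny offset (default 1% of the blob standard deviation).  The two
    variants share identical coordinates for a given seed and differ
    only in whether the duplicate carries the same or the opposite
    label — isolating local connectedness exactly.
``parallel``
    two long thin horizontal strips separated by more than their width.
``unequal``
    well-separated blobs of 20 (tight) and 80 (spread) points.
``concentric``
    a tight central blob inside a ring whose nearest-neighbour spacing
    along the ring is much smaller than the ring-core gap.
``random_big``
    a 1,000-point uniform pattern (no structure; used for comparing
    clustering methods), labelled by the bisector for completeness.

All randomness flows from the explicit ``seed`` through a local
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ARCHETYPES", "PATTERNS", "PointPattern", "generate", "iris_fixture"]

ARCHETYPES = (
    "random_split",
    "transitional",
    "distinct",
    "offset_pairs_same",
    "offset_pairs_diff",
    "parallel",
    "unequal",
    "concentric",
)
PATTERNS = ARCHETYPES + ("random_big",)


@dataclass(frozen=True)
class PointPattern:
    """Planar point set with reference labels."""

    coords: np.ndarray      # (n, 2)
    labels: np.ndarray      # (n,)
    pattern_id: str
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def distances(self) -> np.ndarray:
        """Euclidean distance matrix of the coordinates."""
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coords))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.coords[:, 0], "y": self.coords[:, 1], "label": self.labels}
        )


def _blobs(rng, centers, sds, counts):
    pts, labs = [], []
    for c, (ctr, sd, cnt) in enumerate(zip(centers, sds, counts), start=1):
        pts.append(rng.normal(0.0, sd, size=(cnt, 2)) + np.asarray(ctr))
        labs.append(np.full(cnt, c))
    return np.vstack(pts), np.concatenate(labs)


def _offset_pair_coords(rng, offset_frac):
    """Shared geometry of the two duplicate-pair archetypes."""
    sd = 1.0
    base, base_lab = _blobs(rng, [(0.0, 0.0), (2.2, 0.0)], [sd, sd], [25, 25])
    theta = rng.uniform(0.0, 2.0 * np.pi, size=50)
    step = offset_frac * sd
    dup = base + step * np.column_stack([np.cos(theta), np.sin(theta)])
    coords = np.vstack([base, dup])
    return coords, base_lab


def generate(
    pattern_id: str,
    seed: int,
    n: int | None = None,
    params: dict | None = None,
) -> PointPattern:
    """Generate one archetype reproducibly.

    Parameters
    ----------
    pattern_id
        One of :data:`PATTERNS`.
    seed
        RNG seed; identical calls return bit-identical coordinates.
    n
        Point count override; only honoured by ``random_big`` (default
        1,000).  The eight archetypes are fixed at 100 points.
    params
        Optional overrides of pattern-specific geometry (e.g.
        ``offset_frac`` for the duplicate-pair archetypes).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if pattern_id == "random_split":
        coords = rng.uniform(0.0, 10.0, size=(100, 2))
        labels = np.where(coords[:, 0] < 5.0, 1, 2)
    elif pattern_id == "transitional":
        coords, labels = _blobs(
            rng, [(0.0, 0.0), (6.0, 0.0)], [0.8, 0.8], [46, 46]
        )
        bridge = np.column_stack(
            [rng.uniform(1.8, 4.2, size=8), rng.normal(0.0, 0.3, size=8)]
        )
        bl = np.where(np.abs(bridge[:, 0] - 0.0) < np.abs(bridge[:, 0] - 6.0), 1, 2)
        coords = np.vstack([coords, bridge])
        labels = np.concatenate([labels, bl])
    elif pattern_id == "distinct":
        coords, labels = _blobs(
            rng, [(0.0, 0.0), (10.0, 0.0)], [0.7, 0.7], [50, 50]
        )
    elif pattern_id in ("offset_pairs_same", "offset_pairs_diff"):
        frac = float(params.get("offset_frac", 0.01))
        coords, base_lab = _offset_pair_coords(rng, frac)
        if pattern_id == "offset_pairs_same":
            labels = np.concatenate([base_lab, base_lab])
        else:
            labels = np.concatenate([base_lab, 3 - base_lab])
    elif pattern_id == "parallel":
        x = rng.uniform(0.0, 12.0, size=100)
        y = rng.uniform(0.0, 0.5, size=100)
        gap = float(params.get("gap", 3.0))
        y[50:] += 0.5 + gap
        coords = np.column_stack([x, y])
        labels = np.repeat([1, 2], 50)
    elif pattern_id == "unequal":
        coords, labels = _blobs(
            rng, [(0.0, 0.0), (7.0, 0.0)], [0.3, 1.2], [20, 80]
        )
    elif pattern_id == "concentric":
        core = rng.normal(0.0, 0.3, size=(50, 2))
        radius = float(params.get("radius", 6.0))
        angles = 2.0 * np.pi * (np.arange(50) + rng.uniform(-0.2, 0.2, 50)) / 50.0
        r = radius + rng.normal(0.0, 0.1, size=50)
        ring = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
        coords = np.vstack([core, ring])
        labels = np.repeat([1, 2], 50)
    elif pattern_id == "random_big":
        n = 1000 if n is None else int(n)
        coords = rng.uniform(0.0, 10.0, size=(n, 2))
        labels = np.where(coords[:, 0] < 5.0, 1, 2)
    else:
        raise ValueError(f"unknown pattern_id {pattern_id!r}; choose from {PATTERNS}")

    return PointPattern(
        coords=coords, labels=labels, pattern_id=pattern_id, seed=seed
    )


def iris_fixture() -> PointPattern:
    """Fisher's Iris, restricted to sepal length and petal length.

    The two variables are standardized to mean 0 and standard
    deviation 1 (n-1 denominator); species are the reference partition
    (three clusters of 50).
    """
    from sklearn.datasets import load_iris

    iris = load_iris()
    X = iris.data[:, [0, 2]].astype(float)  # sepal length, petal length
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    labels = np.asarray(iris.target_names)[iris.target]
    return PointPattern(coords=X, labels=labels, pattern_id="iris", seed=None)
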