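"""Shared fixtures and independently coded oracles.

The oracle functions below re-derive the quantities under test from
their definitions with plain Python loops and ``math`` primitives, on
purpose sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def oracle_power_mean(values, p: float) -> float:
    """Direct evaluation of the power-mean definition (loop + math)."""
    values = [float(v) for v in values]
    n = len(values)
    if p == -math.inf:
        return min(values)
    if p == math.inf:
        return max(values)
    if p == 0:
        if any(v == 0 for v in values):
            return 0.0
        return math.exp(math.fsum(math.log(v) for v in values) / n)
    if p < 0 and any(v == 0 for v in values):
        return 0.0
    return (math.fsum(v**p for v in values) / n) ** (1.0 / p)


def oracle_silhouette(D, labels, p: float):
    """Loop-based per-object silhouette widths at exponent p."""
    D = np.asarray(D, float)
    labels = list(labels)
    n = len(labels)
    out = []
    for i in range(n):
        own = labels[i]
        mine = [D[i, j] for j in range(n) if j != i and labels[j] == own]
        if not mine:
            out.append(0.0)
            continue
        a = oracle_power_mean(mine, p)
        b = math.inf
        for c in sorted(set(labels), key=repr):
            if c == own:
                continue
            b = min(b, oracle_power_mean(
                [D[i, j] for j in range(n) if labels[j] == c], p))
        m = max(a, b)
        out.append(0.0 if m == 0 else (b - a) / m)
    return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_distances(rng):
    """Factory for random Euclidean distance matrices."""

    def make(n: int, d: int = 2):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(rng.normal(size=(n, d))))

    return make


@pytest.fixture
def line_example():
    """Four collinear points 0, 1, 10, 11 in two obvious clusters."""
    x = np.array([0.0, 1.0, 10.0, 11.0])
    D = np.abs(x[:, None] - x[None, :])
    labels = np.array([1, 1, 2, 2])
    return D, labels
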