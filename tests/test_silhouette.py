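"""Silhouette engine: hand examples, reference cross-checks, invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_samples

from gensil import (
    DEFAULT_P_GRID,
    silhouette_profile,
    silhouette_widths,
    summaries_frame,
    validity_summary,
)

from conftest import oracle_silhouette


class TestLineExample:
    """Four collinear points 0, 1, 10, 11 labelled {1,1,2,2}."""

    def test_classic_p1(self, line_example):
        D, labels = line_example
        tab = silhouette_widths(D, labels, 1.0)
        # focal point at 0: a = 1, b = (10 + 11)/2 = 10.5
        assert tab.loc[0, "a"] == pytest.approx(1.0)
        assert tab.loc[0, "b"] == pytest.approx(10.5)
        assert tab.loc[0, "s"] == pytest.approx(9.5 / 10.5)
        ref = silhouette_samples(D, labels, metric="precomputed")
        np.testing.assert_allclose(tab["s"], ref, atol=1e-10)

    def test_min_and_max_limits(self, line_example):
        D, labels = line_example
        lo = silhouette_widths(D, labels, -np.inf)
        assert lo.loc[0, "b"] == pytest.approx(10.0)
        assert lo.loc[0, "s"] == pytest.approx(0.9)
        hi = silhouette_widths(D, labels, np.inf)
        assert hi.loc[0, "b"] == pytest.approx(11.0)
        assert hi.loc[0, "s"] == pytest.approx(10.0 / 11.0)

    def test_neighbor_ids(self, line_example):
        D, labels = line_example
        tab = silhouette_widths(D, labels, 1.0)
        assert (tab["neighbor"] != tab["cluster"]).all()
        assert (tab["neighbor"] == np.array([2, 2, 1, 1])).all()


@pytest.mark.parametrize("p", [-np.inf, -1.0, 0.0, 1.0, 2.0, np.inf])
def test_matches_loop_oracle(random_distances, p):
    rng = np.random.default_rng(99)
    for _ in range(5):
        D = random_distances(15)
        labels = rng.integers(0, 3, size=15)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, size=15)
        tab = silhouette_widths(D, labels, p)
        np.testing.assert_allclose(
            tab["s"], oracle_silhouette(D, labels, p), atol=1e-12
        )


def test_classic_equivalence_with_sklearn(random_distances):
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(10, 60))
        D = random_distances(n)
        k = int(rng.integers(2, 6))
        labels = rng.integers(0, k, size=n)
        if len(np.unique(labels)) < 2:
            continue
        tab = silhouette_widths(D, labels, 1.0)
        ref = silhouette_samples(D, labels, metric="precomputed")
        np.testing.assert_allclose(tab["s"], ref, atol=1e-10)


def test_singleton_cluster_scores_zero(random_distances):
    D = random_distances(8)
    labels = np.array([1, 1, 1, 1, 1, 1, 1, 9])
    for p in DEFAULT_P_GRID:
        tab = silhouette_widths(D, labels, p)
        assert tab.loc[7, "s"] == 0.0
        assert tab.loc[7, "a"] == 0.0
        assert tab.loc[7, "neighbor"] == 1


def test_constant_distances_give_zero_everywhere():
    n = 10
    D = np.full((n, n), 3.0)
    np.fill_diagonal(D, 0.0)
    labels = np.repeat([0, 1], 5)
    for summ in silhouette_profile(D, labels, DEFAULT_P_GRID):
        assert summ.msw == pytest.approx(0.0)
        assert summ.mr == 0.0


def test_duplicate_objects_zero_distance_handled():
    # four coincident objects split across two clusters: every focal
    # object has a = b = 0, which resolves to s = 0 rather than 0/0
    D = np.zeros((4, 4))
    labels = np.array([1, 2, 1, 2])
    for p in (-np.inf, -1.0, 0.0, 1.0, np.inf):
        tab = silhouette_widths(D, labels, p)
        assert np.all(tab["s"] == 0.0)


def test_label_relabeling_equivariance(random_distances):
    D = random_distances(20)
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=20)
    tab = silhouette_widths(D, labels, -2.0)
    mapping = {0: "d", 1: "c", 2: "b", 3: "a"}
    relabeled = np.array([mapping[l] for l in labels])
    tab2 = silhouette_widths(D, relabeled, -2.0)
    np.testing.assert_allclose(tab["s"], tab2["s"], atol=1e-14)
    assert all(mapping[l] == l2 for l, l2 in zip(tab["neighbor"], tab2["neighbor"]))


def test_object_permutation_equivariance(random_distances):
    D = random_distances(16)
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 3, size=16)
    perm = rng.permutation(16)
    tab = silhouette_widths(D, labels, 0.0)
    tab_p = silhouette_widths(D[np.ix_(perm, perm)], labels[perm], 0.0)
    np.testing.assert_allclose(tab["s"].to_numpy()[perm], tab_p["s"], atol=1e-12)


def test_distance_scale_invariance(random_distances):
    D = random_distances(25)
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 3, size=25)
    for p in (-np.inf, -1.0, 0.5, 2.0, np.inf):
        s1 = silhouette_widths(D, labels, p)["s"]
        s2 = silhouette_widths(17.3 * D, labels, p)["s"]
        np.testing.assert_allclose(s1, s2, atol=1e-12)


def test_bounds_and_sign(random_distances):
    rng = np.random.default_rng(8)
    for _ in range(5):
        D = random_distances(30)
        labels = rng.integers(0, 4, size=30)
        for p in (-np.inf, -3.0, 0.0, 1.0, 3.0, np.inf):
            tab = silhouette_widths(D, labels, p)
            assert tab["s"].between(-1.0, 1.0).all()
            nonsingleton = tab["a"] > 0
            pos = tab.loc[nonsingleton, "s"] > 0
            gt = tab.loc[nonsingleton, "b"] > tab.loc[nonsingleton, "a"]
            assert (pos == gt).all()


def test_a_and_b_nondecreasing_in_p(random_distances):
    rng = np.random.default_rng(21)
    D = random_distances(20)
    labels = rng.integers(0, 3, size=20)
    grid = [-np.inf, -2.0, -0.5, 0.0, 0.5, 1.0, 2.0, np.inf]
    tabs = [silhouette_widths(D, labels, p) for p in grid]
    for prev, cur in zip(tabs, tabs[1:]):
        assert (cur["a"] >= prev["a"] - 1e-10).all()
        assert (cur["b"] >= prev["b"] - 1e-10).all()


def test_summary_arithmetic():
    tab = pd.DataFrame(
        {
            "object_id": range(4),
            "cluster": [1, 1, 2, 2],
            "neighbor": [2, 2, 1, 1],
            "a": [0.1] * 4,
            "b": [0.2] * 4,
            "s": [0.5, -0.2, 0.9, -0.1],
        }
    )
    tab.attrs["p"] = 1.0
    summ = validity_summary(tab)
    assert summ.msw == pytest.approx(0.275)
    assert summ.mr == pytest.approx(0.5)
    # MSW is the size-weighted mean of the per-cluster means
    sizes = tab.groupby("cluster")["s"].size()
    assert summ.msw == pytest.approx(
        float((summ.cluster_msw * sizes).sum() / sizes.sum())
    )


def test_msw_always_arithmetic_even_for_other_p(random_distances):
    D = random_distances(12)
    labels = np.repeat([0, 1], 6)
    tab = silhouette_widths(D, labels, -3.0)
    assert validity_summary(tab).msw == pytest.approx(float(tab["s"].mean()))


def test_profile_orders_and_frame(random_distances):
    D = random_distances(10)
    labels = np.repeat([0, 1], 5)
    grid = [1.0, -np.inf, 0.0]
    df = summaries_frame(silhouette_profile(D, labels, grid))
    assert list(df["p"]) == grid
    assert df["msw"].between(-1, 1).all()


def test_errors():
    D = np.zeros((3, 3))
    with pytest.raises(ValueError):
        silhouette_widths(D, [1, 1, 1], 1.0)  # k < 2
    with pytest.raises(ValueError):
        silhouette_widths(D, [1, 2], 1.0)  # size mismatch
    with pytest.raises(ValueError):
        silhouette_widths(np.ones((3, 3)), [1, 1, 2], 1.0)  # bad diagonal
    with pytest.raises(ValueError):
        silhouette_profile(D, [1, 1, 2], [])  # empty grid
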