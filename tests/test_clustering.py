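"""Gower dissimilarity, Ward linkage (vs oracles), cutting, LOOCV, markers."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score

from digepipe.clustering import (
    cluster_profiles,
    correlate_cluster_with_external,
    cut_to_k,
    gower_matrix,
    linkage_to_newick,
    loocv_stability,
    marker_cluster_score,
    ward_linkage,
)
from digepipe.io import SpotAnnotation
from digepipe.normalize import average_replicates, total_volume_normalize, unite_fractions
from digepipe.pipeline import pattern_profiles


def naive_ward(d, variant="D2"):
    """Independent O(n^3) Ward: explicit cluster lists, recomputed merge cost
    from the Lance-Williams recurrence at every step."""
    n = d.shape[0]
    w = d.astype(float) ** 2 if variant == "D2" else d.astype(float).copy()
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    for step in range(n - 1):
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                if best is None or w[i, j] < best[2] - 1e-15:
                    if best is None or w[i, j] < best[2]:
                        best = (i, j, w[i, j])
        i, j, dist = best
        merges.append((ids[i], ids[j],
                       np.sqrt(dist) if variant == "D2" else dist,
                       len(clusters[i]) + len(clusters[j])))
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in sorted(clusters):
            if k in (i, j):
                continue
            nk = len(clusters[k])
            new = ((ni + nk) * w[i, k] + (nj + nk) * w[j, k] - nk * dist) / (
                ni + nj + nk
            )
            w[i, k] = w[k, i] = new
        clusters[i] = clusters[i] + clusters[j]
        ids[i] = next_id
        next_id += 1
        del clusters[j]
    return np.array(merges)


def test_gower_hand_example():
    """x = ((0,0),(1,2),(2,4)): ranges (2,4); d(1,2) = (0.5+0.5)/2 = 0.5."""
    profiles = pd.DataFrame([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]],
                            index=["a", "b", "c"])
    d = gower_matrix(profiles)
    assert d.loc["a", "b"] == pytest.approx(0.5)
    assert d.loc["b", "c"] == pytest.approx(0.5)
    assert d.loc["a", "c"] == pytest.approx(1.0)
    assert np.allclose(np.diag(d), 0.0)


def test_gower_identical_and_extreme_profiles():
    same = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
    assert gower_matrix(same).iloc[0, 1] == 0.0
    extremes = pd.DataFrame([[0.0, 0.0], [3.0, 7.0]])
    assert gower_matrix(extremes).iloc[0, 1] == pytest.approx(1.0)


def test_gower_scale_invariance():
    rng = np.random.default_rng(1)
    profiles = pd.DataFrame(rng.normal(size=(10, 5)))
    base = gower_matrix(profiles)
    scaled = profiles.copy()
    scaled[2] = scaled[2] * 37.5
    pd.testing.assert_frame_equal(base, gower_matrix(scaled))


def test_gower_zero_range_column_dropped_with_warning():
    profiles = pd.DataFrame([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]],
                            columns=["v", "const"])
    with pytest.warns(UserWarning, match="const"):
        d = gower_matrix(profiles)
    assert d.iloc[0, 2] == pytest.approx(1.0)  # only the varying sample counts


def test_ward_two_points():
    z = ward_linkage(np.array([[0.0, 0.6], [0.6, 0.0]]))
    assert z.shape == (1, 4)
    assert z[0, 2] == pytest.approx(0.6)


def test_ward_two_tight_pairs_merge_first():
    # points on a line: {0, 0.1} and {10, 10.1}
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(pts[:, None] - pts[None, :])
    z = ward_linkage(d)
    first_two = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}


@pytest.mark.parametrize("variant", ["D1", "D2"])
@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_ward_matches_naive_oracle(variant, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 11))
    x = rng.uniform(size=(n, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    z = ward_linkage(d, variant=variant)
    oracle = naive_ward(d, variant=variant)
    assert np.allclose(z, oracle)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_ward_d2_matches_scipy(seed):
    """The D2 variant reproduces scipy's ward linkage heights/partitions."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(12, 4))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    z_mine = ward_linkage(d)
    z_scipy = sch.linkage(sch.distance.squareform(d, checks=False),
                          method="ward")
    assert np.allclose(np.sort(z_mine[:, 2]), np.sort(z_scipy[:, 2]))
    for k in range(2, 8):
        a = cut_to_k(z_mine, k).to_numpy()
        b = sch.fcluster(z_scipy, t=k, criterion="maxclust")
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


def test_ward_heights_monotone_and_order_invariant():
    rng = np.random.default_rng(9)
    profiles = pd.DataFrame(rng.normal(size=(15, 6)),
                            index=[f"s{i}" for i in range(15)])
    res = cluster_profiles(profiles, k=4)
    assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()
    perm = rng.permutation(15)
    shuffled = profiles.iloc[perm]
    res2 = cluster_profiles(shuffled, k=4)
    joined = pd.concat([res.assignment, res2.assignment], axis=1).to_numpy()
    assert adjusted_rand_score(joined[:, 0], joined[:, 1]) == pytest.approx(1.0)


def test_ward_rejects_bad_input():
    with pytest.raises(Exception, match="symmetric"):
        ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(Exception, match="negative"):
        ward_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_cut_extremes():
    rng = np.random.default_rng(2)
    d = np.abs(rng.normal(size=(6, 6)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    z = ward_linkage(d)
    assert cut_to_k(z, 1).nunique() == 1
    assert cut_to_k(z, 6).nunique() == 6
    with pytest.raises(Exception, match="out of range"):
        cut_to_k(z, 7)


def test_loocv_stability_duplicated_columns_is_one():
    rng = np.random.default_rng(5)
    col = rng.normal(size=12)
    profiles = pd.DataFrame(
        {f"c{i}": col * (i % 3 + 1) + (i % 3) for i in range(6)},
        index=[f"s{i}" for i in range(12)],
    )
    # structure is carried redundantly by every column
    stab = loocv_stability(profiles, k=2)
    assert (stab >= 0.999).all()


def test_planted_clusters_recovered(sim_default):
    """Marker-panel spots, clustered by their expression patterns at the
    panel count, recover the planted memberships (ARI >= 0.9)."""
    matrices = [
        average_replicates(
            total_volume_normalize(sim_default.tables[f], sim_default.design),
            sim_default.design,
        )
        for f in sim_default.tables
    ]
    united = unite_fractions(matrices)
    labels = sim_default.truth.marker_labels()
    profiles = pattern_profiles(united, keys=labels.index)
    res = cluster_profiles(profiles, k=labels.nunique())
    ari = adjusted_rand_score(labels.to_numpy(), res.assignment.to_numpy())
    assert ari >= 0.9


def test_loocv_planted_clusters_stable(sim_default):
    matrices = [
        average_replicates(
            total_volume_normalize(sim_default.tables[f], sim_default.design),
            sim_default.design,
        )
        for f in sim_default.tables
    ]
    united = unite_fractions(matrices)
    labels = sim_default.truth.marker_labels()
    profiles = pattern_profiles(united, keys=labels.index)
    stab = loocv_stability(profiles, k=labels.nunique())
    assert (stab >= 0.9).all()


def test_marker_labelling_and_scores():
    annotation = SpotAnnotation(
        table=pd.DataFrame(
            {
                "fraction": ["cytosol"] * 4,
                "spot_id": ["s1", "s2", "s3", "s4"],
                "gene_symbol": ["HBA1", "HBB", "CAT", "FGB"],
                "confidence": ["identified_ms"] * 4,
                "isoform_group": ["g1", "g2", "g3", "g4"],
                "mw_class": [None] * 4,
            }
        )
    )
    idx = pd.MultiIndex.from_product([["cytosol"], ["s1", "s2", "s3", "s4"]],
                                     names=["fraction", "spot_id"])
    assignment = pd.Series([1, 1, 1, 2], index=idx)
    ratios = pd.DataFrame({"p1": [2.0, 2.0, 2.0, 1.0]}, index=idx)
    labels, scores = marker_cluster_score(assignment, annotation,
                                          hl_ratios=ratios)
    assert labels == {1: "erythrocyte"}  # cluster 2 has only one panel gene
    assert scores.loc[1, "p1"] == pytest.approx(2.0)


def test_correlate_cluster_with_external_cases():
    scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    r, _ = correlate_cluster_with_external(scores, scores * 3.0)
    assert r == pytest.approx(1.0)
    with pytest.raises(Exception, match="constant"):
        correlate_cluster_with_external(scores, scores * 0.0 + 2.0)
    with pytest.raises(Exception, match=">= 3"):
        correlate_cluster_with_external(scores.iloc[:2], scores.iloc[:2])


def test_newick_rendering_is_parseable():
    d = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]])
    z = ward_linkage(d)
    text = linkage_to_newick(z, ["a", "b", "c"])
    assert text.endswith(";") and text.count("(") == 2
    assert all(label in text for label in ("a", "b", "c"))
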