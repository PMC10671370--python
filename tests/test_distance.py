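"""Distance matrices, ordination, Mantel, AMOVA."""

import numpy as np
import pandas as pd
import pytest

from dartpool import (
    abs_diff_matrix,
    amova,
    geographic_distance,
    gower_dissimilarity,
    jaccard_distance,
    mantel,
    pca,
    pcoa,
)
from dartpool.distance import DistanceMatrix


def _binary(rows, labels=None):
    labels = labels or [f"A{i + 1}" for i in range(len(rows))]
    return pd.DataFrame(np.asarray(rows, float), index=labels,
                        columns=[f"c{j}" for j in range(len(rows[0]))])


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

def test_jaccard_identical_rows_zero():
    dm = jaccard_distance(_binary([[1, 1, 0, 1], [1, 1, 0, 1]]))
    assert dm.values[0, 1] == 0.0


def test_jaccard_hand_count():
    # M11 = 2, M10 = 1, M01 = 0 -> d = 1/3
    dm = jaccard_distance(_binary([[1, 1, 0, 1], [1, 0, 0, 1]]))
    assert dm.values[0, 1] == pytest.approx(1 / 3)


def test_jaccard_disjoint_rows_one():
    dm = jaccard_distance(_binary([[1, 1, 0, 0], [0, 0, 1, 1]]))
    assert dm.values[0, 1] == 1.0


def test_jaccard_pairwise_complete_ignores_missing_columns():
    rows = _binary([[1, 1, 0, 1], [1, 0, 0, 1]])
    rows.iloc[0, 1] = np.nan     # drops the single mismatching column
    dm = jaccard_distance(rows)
    assert dm.values[0, 1] == 0.0


def test_jaccard_all_missing_row_errors():
    rows = _binary([[1, 0], [np.nan, np.nan]])
    with pytest.raises(ValueError, match="A2"):
        jaccard_distance(rows)


# ---------------------------------------------------------------------------
# Gower
# ---------------------------------------------------------------------------

def test_gower_range_endpoints_and_hand_value():
    t = pd.DataFrame({"v": [0.0, 5.0, 10.0]}, index=["s1", "s2", "s3"])
    dm = gower_dissimilarity(t)
    assert dm.values[0, 2] == 1.0
    assert dm.values[0, 1] == pytest.approx(0.5)


def test_gower_duplicated_variable_invariant():
    t = pd.DataFrame({"v": [0.0, 2.0, 9.0], "w": [1.0, 4.0, 6.0]})
    t2 = pd.concat([t, t.add_suffix("_copy")], axis=1)
    np.testing.assert_allclose(
        gower_dissimilarity(t).values, gower_dissimilarity(t2).values
    )


def test_gower_zero_range_dropped_with_warning():
    t = pd.DataFrame({"v": [0.0, 1.0], "const": [5.0, 5.0]})
    with pytest.warns(UserWarning, match="const"):
        dm = gower_dissimilarity(t)
    assert dm.values[0, 1] == 1.0
    with pytest.raises(ValueError):
        gower_dissimilarity(pd.DataFrame({"const": [5.0, 5.0]}))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_collinear_points_single_axis():
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
    res = pcoa(DistanceMatrix(labels=list("abc"), values=d))
    assert res.pct_explained[0] == pytest.approx(100.0)
    got = res.coordinates.iloc[:, 0].values
    recon = np.abs(got[:, None] - got[None, :])
    np.testing.assert_allclose(recon, d, atol=1e-10)


def test_pcoa_all_zero_distances():
    res = pcoa(DistanceMatrix(labels=list("abc"), values=np.zeros((3, 3))))
    assert res.coordinates.shape[1] == 0
    assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pcoa_reconstructs_euclidean_distances(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(12, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix(labels=[str(i) for i in range(12)], values=d))
    coords = res.coordinates.values
    recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    np.testing.assert_allclose(recon, d, atol=1e-8)


def test_pcoa_agrees_with_reference_implementation():
    import warnings

    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix(labels=[str(i) for i in range(8)], values=d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    np.testing.assert_allclose(
        np.sort(res.eigenvalues[res.eigenvalues > 1e-9])[::-1],
        np.sort(ref.eigvals[ref.eigvals > 1e-9].values)[::-1],
        atol=1e-8,
    )


def test_pcoa_rejects_asymmetric():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=list("ab"), values=np.array([[0, 1], [2, 0.0]]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_duplicated_variable_single_component():
    t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    res = pca(t)
    assert res.pct_explained[0] == pytest.approx(100.0)


def test_pca_uncorrelated_variables_split_variance():
    rng = np.random.default_rng(0)
    t = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
    res = pca(t)
    assert res.pct_explained[0] == pytest.approx(50.0, abs=5.0)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(1)
    t = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    r1, r2 = pca(t), pca(t.copy())
    pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
    for k in range(r1.loadings.shape[1]):
        col = r1.loadings.iloc[:, k]
        assert col.iloc[np.argmax(np.abs(col.values))] > 0


def test_pca_single_row_errors():
    with pytest.raises(ValueError):
        pca(pd.DataFrame({"a": [1.0]}))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _random_dm(seed, n=8):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(labels=[str(i) for i in range(n)], values=d)


def test_mantel_self_correlation():
    d1 = _random_dm(0)
    res = mantel(d1, d1, n_perm=99, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_affine_invariance():
    d1 = _random_dm(2)
    d2 = DistanceMatrix(labels=d1.labels, values=2.5 * d1.values)
    res = mantel(d1, d2, n_perm=49, seed=0)
    assert res.r == pytest.approx(1.0)


def test_mantel_label_mismatch():
    d1, d2 = _random_dm(0), _random_dm(1)
    d2.labels = list(reversed(d2.labels))
    with pytest.raises(ValueError):
        mantel(d1, d2, n_perm=9)


def test_mantel_p_honors_plus_one_bound():
    res = mantel(_random_dm(0), _random_dm(5), n_perm=99, seed=3)
    assert res.p_value >= 1 / 100


# ---------------------------------------------------------------------------
# geographic / abs-diff
# ---------------------------------------------------------------------------

def test_haversine_degree_of_latitude():
    sites = pd.DataFrame({"lat": [0.0, 1.0], "lon": [0.0, 0.0]}, index=["a", "b"])
    dm = geographic_distance(sites)
    assert dm.values[0, 1] == pytest.approx(111.19, abs=0.01)
    assert dm.values[0, 0] == 0.0


def test_geographic_out_of_range():
    sites = pd.DataFrame({"lat": [95.0], "lon": [0.0]}, index=["a"])
    with pytest.raises(ValueError):
        geographic_distance(sites)


def test_abs_diff_altitudes():
    dm = abs_diff_matrix(pd.Series([100.0, 1600.0], index=["a", "b"]))
    assert dm.values[0, 1] == 1500.0


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def test_amova_perfect_separation():
    # within-group d = 0, between-group d = 1, 2+2 design
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    dm = DistanceMatrix(labels=list("abcd"), values=d)
    res = amova(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, n_perm=99, seed=0)
    assert res.pct_among == pytest.approx(100.0)
    assert res.phi_st == pytest.approx(1.0)
    assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-12)


def test_amova_hand_ss_partition():
    # same design: 4 between-group pairs with d = 1, so
    # SS_total = sum_{i<j} d^2 / N = 4/4 = 1; SS_within = 0
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    dm = DistanceMatrix(labels=list("abcd"), values=d)
    res = amova(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, n_perm=9, seed=0)
    assert res.ss_total == pytest.approx(1.0)
    assert res.ss_within == pytest.approx(0.0)
    assert res.ss_among == pytest.approx(1.0)


def test_amova_ss_identity_random_inputs():
    rng = np.random.default_rng(4)
    for _ in range(5):
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(labels=[str(i) for i in range(10)], values=d)
        groups = {str(i): "g1" if i < 5 else "g2" for i in range(10)}
        res = amova(dm, groups, n_perm=9, seed=0)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-10)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)


def test_amova_exchangeable_data_null():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(12, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    dm = DistanceMatrix(labels=[str(i) for i in range(12)], values=d)
    groups = {str(i): "g1" if i % 2 else "g2" for i in range(12)}
    res = amova(dm, groups, n_perm=199, seed=1)
    assert res.phi_st < 0.25
    assert res.p_value > 0.05


def test_amova_single_group_and_singleton_errors():
    d = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(labels=list("abcd"), values=d)
    with pytest.raises(ValueError):
        amova(dm, {k: "g" for k in "abcd"})
    with pytest.raises(ValueError, match="singleton"):
        amova(dm, {"a": "g1", "b": "g1", "c": "g1", "d": "g2"})
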