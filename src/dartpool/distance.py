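"""Dissimilarity matrices, ordination and matrix-association tests.

Genetic distance between pooled accessions is the Jaccard dissimilarity of
the codominant binary expansion (two presence columns per locus), computed
over pairwise-complete columns.  Site and phenotype tables use the Gower
range-normalized dissimilarity.  Ordination is metric PCoA (Gower double
centering) or PCA on standardized variables; association between matrices
uses the one-sided Mantel permutation test; the among/within-group
partition of squared distances is an Excoffier-style one-level AMOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(v[finite] < 0):
                raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def mean_offdiag(self) -> float:
        return float(np.nanmean(self.condensed()))


# ---------------------------------------------------------------------------
# distance constructions
# ---------------------------------------------------------------------------

def jaccard_distance(bm: pd.DataFrame) -> DistanceMatrix:
    """Jaccard dissimilarity between rows of a presence/absence matrix.

    For each pair of rows, over columns where both are non-missing,
    ``d = 1 - M11 / (M11 + M10 + M01)``.  Pairs with no informative column
    (no column where at least one row shows presence) get NaN.
    """
    if bm.shape[0] < 2:
        raise ValueError("need at least two rows")
    all_na = bm.isna().all(axis=1)
    if all_na.any():
        raise ValueError(f"accession {bm.index[all_na][0]!r} is all-missing")
    x = bm.to_numpy(float)
    present = ~np.isnan(x)
    ones = np.where(present, x, 0.0)
    # pairwise-complete: both non-missing
    m11 = ones @ ones.T
    both = present.astype(float) @ present.astype(float).T
    row_ones = ones @ present.astype(float).T    # i has 1 where both observed
    m10 = row_ones - m11
    m01 = row_ones.T - m11
    denom = m11 + m10 + m01
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - m11 / denom
    d[denom == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=list(bm.index), values=d, metric="jaccard")


def gower_dissimilarity(table: pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity for quantitative variables.

    Mean over variables of ``|x_i - x_j| / range``; variables with zero
    range are dropped with a warning, and missing values are handled
    pairwise-complete.
    """
    import warnings

    ranges = table.max() - table.min()
    keep = ranges > 0
    if not keep.any():
        raise ValueError("all variables have zero range")
    if (~keep).any():
        warnings.warn(
            f"dropping zero-range variable(s): {list(table.columns[~keep])}",
            stacklevel=2,
        )
    t = table.loc[:, keep]
    x = t.to_numpy(float) / (t.max() - t.min()).to_numpy(float)
    obs = ~np.isnan(x)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x)          # n x p
        both = obs[i] & obs
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(cnt > 0, np.where(both, diff, 0.0).sum(axis=1) / cnt, np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(table.index), values=d, metric="gower")


def geographic_distance(sites: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distance in km, spherical Earth R = 6371 km.

    *sites* needs ``lat`` and ``lon`` columns in decimal degrees.
    """
    lat = sites["lat"].to_numpy(float)
    lon = sites["lon"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    phi, lam = np.radians(lat), np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(sites.index), values=d, metric="geographic_km")


def abs_diff_matrix(values: pd.Series) -> DistanceMatrix:
    """Absolute pairwise difference of a scalar per object (e.g. altitude)."""
    v = values.to_numpy(float)
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(labels=list(values.index), values=d, metric="abs_diff")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame    # objects x axes
    eigenvalues: np.ndarray      # all, decreasing
    pct_explained: np.ndarray    # over positive eigenvalues, sums to 100

    def cumulative_pct(self, k: int) -> float:
        return float(self.pct_explained[:k].sum())


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Metric principal coordinate analysis of a distance matrix.

    Gower double-centering of ``-D^2/2`` followed by eigendecomposition;
    coordinates are eigenvectors scaled by the square root of positive
    eigenvalues.  Negative eigenvalues are retained in ``eigenvalues``
    but excluded from the percent-explained denominator.
    """
    d = dm.values
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing values")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(1.0, abs(eigval).max())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords = _fix_signs(coords)
    pct = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="PCoA",
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=axes),
        eigenvalues=eigval,
        pct_explained=pct,
    )


def pca(table: pd.DataFrame, standardize: bool = True) -> OrdinationResult:
    """PCA on (unbiased-sd) standardized columns.

    Zero-variance variables are dropped with a warning.  Component signs
    are fixed so the largest-|loading| element of each component is
    positive.
    """
    import warnings

    if table.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    x = table.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance variable(s): {list(table.columns[~keep])}",
            stacklevel=2,
        )
    x = x[:, keep]
    x = x - x.mean(axis=0)
    if standardize:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigval = s**2 / (x.shape[0] - 1)
    # sign convention: largest-|loading| element of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    pos = eigval > 1e-12 * max(1.0, eigval.max())
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    res = OrdinationResult(
        method="PCA",
        coordinates=pd.DataFrame(coords, index=table.index, columns=axes),
        eigenvalues=eigval,
        pct_explained=pct,
    )
    res.loadings = pd.DataFrame(
        vt.T, index=table.columns[keep], columns=axes
    )
    return res


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1
    return coords


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 100_000, seed: int = 0
) -> MantelResult:
    """One-sided (positive association) Mantel permutation test.

    r is the Pearson correlation of the lower triangles;
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)`` under joint row/column
    permutation of the second matrix.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y_full = d2.values
    x = (x - x.mean()) / x.std()
    y = y_full[iu]
    y_std = (y - y.mean()) / y.std()
    r_obs = float(np.mean(x * y_std))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y_full[np.ix_(perm, perm)][iu]
        yp = (yp - yp.mean()) / yp.std()
        if np.mean(x * yp) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AMOVAResult:
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_perm: int
    seed: int
    sigma2_among_truncated: bool = False


def amova(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AMOVAResult:
    """One-level AMOVA: partition squared distances among/within groups.

    ``SS_total = sum_{i<j} d_ij^2 / N``; ``SS_within`` sums each group's
    internal squared distances over its size; variance components follow
    the standard mean-square equations with
    ``n0 = (N - sum n_g^2 / N) / (G - 1)``.  The p-value permutes whole
    objects among groups and counts permuted Phi_ST >= observed.
    """
    labels = dm.labels
    glab = np.array([groups[a] for a in labels])
    uniq, counts = np.unique(glab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least two groups")
    if (counts < 2).any():
        bad = uniq[counts < 2][0]
        raise ValueError(f"group {bad!r} is a singleton")
    d2 = dm.values**2
    if np.isnan(d2).any():
        raise ValueError("distance matrix contains missing values")

    def _phi(glab):
        n_tot = len(glab)
        ss_total = d2[np.triu_indices(n_tot, 1)].sum() / n_tot
        ss_within = 0.0
        sizes = []
        for g in np.unique(glab):
            idx = np.where(glab == g)[0]
            sizes.append(len(idx))
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        g_count = len(sizes)
        df_a, df_w = g_count - 1, n_tot - g_count
        ms_a, ms_w = ss_among / df_a, ss_within / df_w
        n0 = (n_tot - sum(s**2 for s in sizes) / n_tot) / df_a
        sigma_w = ms_w
        sigma_a = (ms_a - ms_w) / n0
        return ss_among, ss_within, ss_total, sigma_a, sigma_w

    ss_a, ss_w, ss_t, sig_a, sig_w = _phi(glab)
    truncated = sig_a < 0
    sig_a_rep = max(sig_a, 0.0)
    total_var = sig_a_rep + sig_w
    phi = sig_a_rep / total_var if total_var > 0 else np.nan

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_lab = rng.permutation(glab)
        _, _, _, pa, pw = _phi(perm_lab)
        pa = max(pa, 0.0)
        tv = pa + pw
        phi_p = pa / tv if tv > 0 else 0.0
        if phi_p >= phi - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AMOVAResult(
        ss_among=ss_a, ss_within=ss_w, ss_total=ss_t,
        sigma2_among=sig_a_rep, sigma2_within=sig_w,
        pct_among=100.0 * sig_a_rep / total_var if total_var > 0 else np.nan,
        pct_within=100.0 * sig_w / total_var if total_var > 0 else np.nan,
        phi_st=phi, p_value=p, n_perm=n_perm, seed=seed,
        sigma2_among_truncated=truncated,
    )
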