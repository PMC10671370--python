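"""Generalized Procrustes Analysis (GPA) of multiple coordinate tables.

GPA aligns m configurations of the same objects by translation, rotation
(full orthogonal group, reflections allowed) and isotropic per-
configuration scaling under the standard constraint that the total sum of
squares of the scaled configurations is preserved.  The consensus is the
mean fitted configuration; discrepancy is the residual sum of squares of
fitted configurations around the consensus.

PANOVA attributes the reduction of discrepancy to the successive steps
translation -> rotation -> scaling (the order affects attribution, not the
fit).  The consensus test permutes object rows independently within every
configuration but the first and compares the consensus proportion rc =
1 - SS_residual / SS_total against its permutation null.

For combining genotype and phenotype data the intended inputs are a PCoA
coordinate table of the genetic distances and a standardized morphometric
table, zero-padded to a common number of dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes


@dataclass
class GPAResult:
    consensus: pd.DataFrame            # objects x dims
    fitted: list[pd.DataFrame]         # per-configuration aligned coordinates
    scale_factors: np.ndarray          # accumulated isotropic scale per config
    residual_ss: float                 # sum over configs of ||fitted - consensus||^2
    total_ss: float                    # sum over configs of ||fitted||^2 (centered)
    per_object_residual: pd.Series
    iterations: int
    converged: bool
    config_names: list[str]

    @property
    def rc(self) -> float:
        """Consensus proportion: SS_consensus / SS_total, in [0, 1]."""
        return 1.0 - self.residual_ss / self.total_ss


def _as_arrays(configs) -> tuple[list[str], list[str], list[np.ndarray]]:
    names, index, mats = [], None, []
    width = max(c.shape[1] for c in configs.values())
    for name, df in configs.items():
        if index is None:
            index = list(df.index)
        elif list(df.index) != index:
            raise ValueError(f"configuration {name!r} has a different object set/order")
        x = df.to_numpy(float)
        if x.shape[1] < width:               # zero-pad to common dimensionality
            x = np.hstack([x, np.zeros((x.shape[0], width - x.shape[1]))])
        names.append(name)
        mats.append(x)
    return names, index, mats


def gpa(
    configs: dict[str, pd.DataFrame],
    scale: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GPAResult:
    """Iterative GPA of >= 2 configurations sharing the same objects."""
    if len(configs) < 2:
        raise ValueError("need at least two configurations")
    names, index, mats = _as_arrays(configs)
    n, d = mats[0].shape
    if n < 3 or d < 2:
        raise ValueError("need >= 3 objects and >= 2 dimensions after padding")
    ys = []
    for name, x in zip(names, mats):
        xc = x - x.mean(axis=0)
        if np.allclose(xc, 0):
            raise ValueError(f"configuration {name!r} is degenerate (all points equal)")
        ys.append(xc)
    total_ss = sum(float((y**2).sum()) for y in ys)
    scales = np.ones(len(ys))

    prev_resid = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # rotate each configuration to the mean of the others; unlike
        # rotating to the full mean (which admits suboptimal fixed points
        # with an indefinite cross-product), the fixed point here is
        # pairwise-Procrustes optimal
        total = np.sum(ys, axis=0)
        for i, y in enumerate(ys):
            target = (total - y) / (len(ys) - 1)
            r, _ = orthogonal_procrustes(y, target)
            ys[i] = y @ r
            total = total - y + ys[i]
        if scale:
            # optimal isotropic scales given the rotations: maximize the
            # summed congruence subject to preserving the total SS; the
            # solution is the leading eigenvector of the normalized
            # inner-product matrix (scaled to the constraint)
            norms = np.array([np.sqrt(float((y**2).sum())) for y in ys])
            phi = np.empty((len(ys), len(ys)))
            for i, yi in enumerate(ys):
                for j, yj in enumerate(ys):
                    phi[i, j] = float((yi * yj).sum()) / (norms[i] * norms[j])
            w, v = np.linalg.eigh(phi)
            lead = v[:, -1]
            if lead.sum() < 0:
                lead = -lead
            step = np.sqrt(total_ss) * lead / norms
            ys = [y * s for y, s in zip(ys, step)]
            scales *= step
        consensus = np.mean(ys, axis=0)
        resid = sum(float(((y - consensus) ** 2).sum()) for y in ys)
        if abs(prev_resid - resid) < tol * max(1.0, total_ss):
            converged = True
            break
        prev_resid = resid

    per_obj = pd.Series(
        np.sum([((y - consensus) ** 2).sum(axis=1) for y in ys], axis=0),
        index=index, name="residual",
    )
    cols = [f"dim{i + 1}" for i in range(d)]
    return GPAResult(
        consensus=pd.DataFrame(consensus, index=index, columns=cols),
        fitted=[pd.DataFrame(y, index=index, columns=cols) for y in ys],
        scale_factors=scales,
        residual_ss=resid,
        total_ss=total_ss,
        per_object_residual=per_obj,
        iterations=it,
        converged=converged,
        config_names=names,
    )


def panova(configs: dict[str, pd.DataFrame], **gpa_kwargs) -> pd.DataFrame:
    """Procrustes analysis of variance.

    Decomposes the initial discrepancy ``G = sum_i ||X_i - mean||^2`` into
    reductions attributable to translation, rotation, scaling, and the
    remaining residual, in that fixed order; the four components sum to
    the total exactly (telescoping differences of the discrepancy after
    each cumulative step).
    """
    names, index, mats = _as_arrays(configs)

    def discrepancy(ms):
        mean = np.mean(ms, axis=0)
        return sum(float(((m - mean) ** 2).sum()) for m in ms)

    g_raw = discrepancy(mats)
    centered = [m - m.mean(axis=0) for m in mats]
    g_centered = discrepancy(centered)
    centered_dfs = {
        n: pd.DataFrame(c, index=index) for n, c in zip(names, centered)
    }
    res_rot = gpa(centered_dfs, scale=False, **gpa_kwargs)
    g_rot = res_rot.residual_ss
    res_full = gpa(centered_dfs, scale=True, **gpa_kwargs)
    g_full = res_full.residual_ss

    rows = [
        {"component": "translation", "ss": g_raw - g_centered},
        {"component": "rotation", "ss": g_centered - g_rot},
        {"component": "scaling", "ss": g_rot - g_full},
        {"component": "residual", "ss": g_full},
        {"component": "total", "ss": g_raw},
    ]
    return pd.DataFrame(rows).set_index("component")


def consensus_test(
    configs: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int = 0,
    **gpa_kwargs,
) -> tuple[float, pd.Series, float]:
    """Permutation test of the consensus proportion rc.

    The null permutes object rows independently within each configuration
    but the first; ``p = (#{rc_perm >= rc_obs} + 1) / (n_perm + 1)``.
    Returns ``(rc_observed, null_summary, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rc_obs = gpa(configs, **gpa_kwargs).rc
    names = list(configs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    base = {n: c.to_numpy(float) for n, c in configs.items()}
    index = list(configs[names[0]].index)
    n_obj = len(index)
    for b in range(n_perm):
        permuted = {names[0]: configs[names[0]]}
        for name in names[1:]:
            perm = rng.permutation(n_obj)
            permuted[name] = pd.DataFrame(base[name][perm], index=index)
        null[b] = gpa(permuted, **gpa_kwargs).rc
    p = (int((null >= rc_obs - 1e-12).sum()) + 1) / (n_perm + 1)
    summary = pd.Series(
        {
            "mean": null.mean(), "sd": null.std(ddof=1),
            "q95": float(np.quantile(null, 0.95)), "max": null.max(),
        },
        name="rc_null",
    )
    return rc_obs, summary, p


def select_dimensions(result: GPAResult, threshold: float = 0.8) -> tuple[int, np.ndarray]:
    """Smallest dimensionality whose consensus variance reaches *threshold*.

    The consensus configuration is rotated to principal axes; per-axis
    variance percentages are returned alongside the selected count.
    """
    c = result.consensus.to_numpy(float)
    c = c - c.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    var = s**2
    if var.sum() == 0:
        raise ValueError("consensus is degenerate")
    pct = 100.0 * var / var.sum()
    cum = np.cumsum(pct) / 100.0
    d = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    d = min(d, len(pct))
    return d, pct
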