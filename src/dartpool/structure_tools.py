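"""Post-processing of external Bayesian clustering runs.

The MCMC itself (STRUCTURE-style admixture clustering) is out of scope;
this module consumes its outputs: a run-summary table of log-probabilities
per K and replicate, from which the Evanno second-difference statistic
selects K, and a Q membership matrix thresholded into pure/mixed labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def read_structure_runs(path) -> pd.DataFrame:
    """CSV with columns K, replicate, ln_prob."""
    df = pd.read_csv(path)
    missing = {"K", "replicate", "ln_prob"} - set(df.columns)
    if missing:
        raise ValueError(f"run table lacks columns: {sorted(missing)}")
    return df


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno's ΔK from replicate log-probabilities per K.

    ``ΔK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`` using replicate
    means; endpoints and zero-sd interior points are NaN (the latter with
    a warning).  Requires a contiguous K range of length >= 3.
    """
    ks = sorted(runs["K"].unique())
    if len(ks) < 3:
        raise ValueError("need at least three K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    stats = runs.groupby("K")["ln_prob"].agg(["mean", "std", "count"])
    stats = stats.reindex(ks)
    delta = pd.Series(np.nan, index=ks, name="delta_k")
    for k in ks[1:-1]:
        sd = stats.loc[k, "std"]
        if not sd or np.isnan(sd) or sd == 0:
            warnings.warn(f"sd(L) = 0 at K={k}; ΔK undefined there", stacklevel=2)
            continue
        second = abs(
            stats.loc[k + 1, "mean"] - 2 * stats.loc[k, "mean"] + stats.loc[k - 1, "mean"]
        )
        delta.loc[k] = second / sd
    out = pd.DataFrame(
        {
            "mean_ln_prob": stats["mean"], "sd_ln_prob": stats["std"],
            "n_replicates": stats["count"], "delta_k": delta,
        }
    )
    out.index.name = "K"
    return out


def best_k(delta_table: pd.DataFrame) -> int:
    """K with the largest ΔK (interior points only)."""
    return int(delta_table["delta_k"].idxmax())


def read_q_matrix(path) -> pd.DataFrame:
    """CSV: accession_id column plus one column per cluster proportion."""
    df = pd.read_csv(path)
    if "accession_id" not in df.columns:
        raise ValueError("Q matrix lacks accession_id column")
    return df.set_index("accession_id")


def assign_memberships(q: pd.DataFrame, threshold: float = 0.8) -> pd.Series:
    """Pure/mixed assignment from a membership matrix.

    An accession is ``pure <cluster>`` iff its proportion for that cluster
    is >= threshold (inclusive), else ``mixed``.  Row sums must be 1
    within 1e-6.
    """
    sums = q.sum(axis=1)
    bad = ~np.isclose(sums, 1.0, atol=1e-6)
    if bad.any():
        raise ValueError(
            f"membership rows do not sum to 1: {list(q.index[bad])}"
        )
    labels = {}
    for acc, row in q.iterrows():
        top = row.idxmax()
        labels[acc] = f"pure {top}" if row[top] >= threshold else "mixed"
    return pd.Series(labels, name="assignment")
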