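"""Accession-level grain morphometry summaries and group comparisons."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import MorphometryRecord, morphometry_frame
from .popgen import AnovaResult, group_stat_anova

PARAMETERS = ("area", "perimeter", "length", "width", "color_r", "color_g", "color_b")


def summarize_morphometry(
    records: list[MorphometryRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-accession means and CV% for the seven grain parameters.

    Returns ``(per_accession, collection)``:

    * ``per_accession`` — one row per accession with ``<param>_mean``,
      ``<param>_cv`` (unbiased-sd CV in percent; 0 with an ``n=1`` flag for
      single-grain accessions) and ``n_grains``;
    * ``collection`` — min / max / mean / CV across accession means per
      parameter.
    """
    df = morphometry_frame(records)
    if df.empty:
        raise ValueError("no morphometry records")
    rows = []
    for acc, grains in df.groupby("accession_id", sort=True):
        row: dict = {"accession_id": acc, "n_grains": len(grains)}
        for p in PARAMETERS:
            vals = grains[p].to_numpy(float)
            row[f"{p}_mean"] = vals.mean()
            if len(vals) > 1 and vals.mean() != 0:
                row[f"{p}_cv"] = vals.std(ddof=1) / vals.mean() * 100.0
            else:
                row[f"{p}_cv"] = 0.0
        row["single_grain"] = len(grains) == 1
        rows.append(row)
    per_acc = pd.DataFrame(rows).set_index("accession_id")

    coll_rows = []
    for p in PARAMETERS:
        means = per_acc[f"{p}_mean"]
        coll_rows.append(
            {
                "parameter": p, "min": means.min(), "max": means.max(),
                "mean": means.mean(),
                "cv_pct": (means.std(ddof=1) / means.mean() * 100.0)
                if len(means) > 1 else 0.0,
            }
        )
    return per_acc, pd.DataFrame(coll_rows).set_index("parameter")


def status_comparison(
    per_accession: pd.DataFrame,
    status: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per grain parameter across biological-status groups.

    Uses accession means as observations.  Returns per-parameter F, p and
    a significance flag at *alpha*.
    """
    labels = pd.Series({a: status[a] for a in per_accession.index})
    if labels.nunique() < 2:
        raise ValueError("need at least two status groups")
    rows = []
    for p in PARAMETERS:
        res = group_stat_anova(
            per_accession[f"{p}_mean"].to_numpy(float), labels.values, alpha
        )
        rows.append(
            {
                "parameter": p, "f_statistic": res.f_statistic,
                "p_value": res.p_value, "significant": bool(res.p_value < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def morphometry_configuration(per_accession: pd.DataFrame) -> pd.DataFrame:
    """Standardized (unbiased sd) 7-variable accession table for ordination."""
    x = per_accession[[f"{p}_mean" for p in PARAMETERS]].copy()
    x.columns = list(PARAMETERS)
    sd = x.std(ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"zero-variance parameters dropped: {list(x.columns[zero])}",
                      stacklevel=2)
        x = x.loc[:, ~zero]
        sd = sd[~zero]
    return (x - x.mean()) / sd
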