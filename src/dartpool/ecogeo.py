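"""Eco-geographical site characterization.

Monthly climate series (TerraClimate vocabulary: tmax, tmin, aet, def,
pet, ppt, PDSI, srad, q, soil, ws) are aggregated per site into annual and
growing-season values, screened for between-site differences by one-way
ANOVA with calendar years as replicates, and the retained parameters are
used to designate groups of sites with extremely contrasting values.

Aggregation rules: temperatures, wind speed and PDSI are monthly states and
are averaged; the water-balance and radiation fluxes (aet, def, pet, ppt,
srad, q, soil) are summed within the scope.  The growing-season month set
defaults to November-May, the winter-cereal season of the Mediterranean
sites this pipeline targets, and is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLIMATE_PARAMETERS
from .popgen import group_stat_anova

#: parameters averaged within a scope; all others are summed
MEAN_PARAMETERS = frozenset({"tmax", "tmin", "ws", "PDSI"})

#: November-May: Mediterranean winter-cereal growing season
DEFAULT_SEASON_MONTHS = (11, 12, 1, 2, 3, 4, 5)


def aggregation_rule(parameter: str) -> str:
    if parameter not in CLIMATE_PARAMETERS:
        raise ValueError(
            f"no aggregation rule for {parameter!r}; "
            f"known parameters: {list(CLIMATE_PARAMETERS)}"
        )
    return "mean" if parameter in MEAN_PARAMETERS else "total"


def _season_year(year: np.ndarray, month: np.ndarray, season: tuple[int, ...]) -> np.ndarray:
    """Assign each month to a season-year; wrapped seasons credit the end year.

    For a season like Nov-May the late-year months (>= the wrap start) are
    attributed to the following calendar year, so one season-year holds one
    contiguous season.
    """
    season = sorted(season)
    wraps = 12 in season and 1 in season and len(season) < 12
    if not wraps:
        return year.copy()
    # wrap start: first month after the largest gap in the sorted set
    gaps = [(season[(i + 1) % len(season)] - m) % 12 for i, m in enumerate(season)]
    start = season[(int(np.argmax(gaps)) + 1) % len(season)]
    out = year.copy()
    out[month >= start] += 1
    return out


def aggregate_climate(
    climate: pd.DataFrame,
    season_months: tuple[int, ...] = DEFAULT_SEASON_MONTHS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a long monthly table into per-site eco-geographical values.

    Returns ``(table, per_year)``:

    * ``table`` — site x (parameter, scope) multi-year means, scopes
      ``annual`` and ``growing_season``;
    * ``per_year`` — the underlying per-(site, parameter, scope, year)
      aggregates retained for ANOVA screening.

    Only complete scopes (all 12, respectively all season, months present)
    enter the aggregation.
    """
    for p in climate["parameter"].unique():
        aggregation_rule(p)  # raises on unknown parameter
    season = set(season_months)
    frames = []
    for scope, months in (("annual", set(range(1, 13))), ("growing_season", season)):
        sub = climate[climate["month"].isin(months)].copy()
        if scope == "growing_season":
            sub["agg_year"] = _season_year(
                sub["year"].to_numpy(int), sub["month"].to_numpy(int), tuple(months)
            )
        else:
            sub["agg_year"] = sub["year"]
        grouped = sub.groupby(["site_id", "parameter", "agg_year"])
        counts = grouped["value"].count()
        sums = grouped["value"].sum()
        means = grouped["value"].mean()
        complete = counts == len(months)
        per_year = pd.DataFrame({"sum": sums, "mean": means})[complete.values]
        per_year = per_year.reset_index()
        per_year["scope"] = scope
        rule = per_year["parameter"].map(
            lambda p: "mean" if p in MEAN_PARAMETERS else "total"
        )
        per_year["value"] = np.where(rule == "mean", per_year["mean"], per_year["sum"])
        frames.append(per_year[["site_id", "parameter", "scope", "agg_year", "value"]])
    per_year = pd.concat(frames, ignore_index=True).rename(columns={"agg_year": "year"})
    if per_year.empty:
        raise ValueError("no complete year in climate table")
    table = (
        per_year.groupby(["site_id", "parameter", "scope"])["value"]
        .mean()
        .unstack(["parameter", "scope"])
    )
    return table, per_year


def screen_parameters(
    per_year: pd.DataFrame, alpha: float = 0.05, scope: str = "annual"
) -> tuple[list[str], pd.DataFrame]:
    """Keep climate parameters whose values differ significantly among sites.

    One-way ANOVA per parameter across sites, with yearly aggregates as
    replicates; parameters with p >= alpha are excluded.  Altitude is not
    screened here (it has no yearly replication) and is always retained by
    downstream consumers.  Returns the retained parameter list and a table
    of per-parameter F and p.
    """
    sub = per_year[per_year["scope"] == scope]
    if sub["site_id"].nunique() < 2:
        raise ValueError("screening needs at least two sites")
    rows = []
    retained = []
    for param in sorted(sub["parameter"].unique()):
        block = sub[sub["parameter"] == param]
        if block.groupby("site_id")["year"].count().min() < 2:
            raise ValueError(f"parameter {param}: a site has < 2 yearly replicates")
        res = group_stat_anova(block["value"].values, block["site_id"].values, alpha)
        keep = bool(res.p_value < alpha) if not np.isnan(res.p_value) else False
        rows.append(
            {"parameter": param, "f_statistic": res.f_statistic,
             "p_value": res.p_value, "retained": keep}
        )
        if keep:
            retained.append(param)
    return retained, pd.DataFrame(rows)


@dataclass(frozen=True)
class ExtremeGroups:
    """Sites at the two extremes of one eco-geographical parameter."""

    parameter: str
    scope: str
    low_sites: tuple[str, ...]
    high_sites: tuple[str, ...]
    method: str                  # "tukey_tails" or "k_extremes"
    k: int | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if set(self.low_sites) & set(self.high_sites):
            raise ValueError("low and high site sets overlap")
        if not self.low_sites or not self.high_sites:
            raise ValueError("no extreme contrast: an extreme group is empty")


def build_extreme_groups(
    per_year: pd.DataFrame,
    parameter: str,
    scope: str = "annual",
    method: str = "tukey_tails",
    k: int = 2,
    alpha: float = 0.05,
) -> ExtremeGroups:
    """Designate low/high site groups for one parameter.

    ``tukey_tails`` takes the Tukey homogeneous letter-group containing the
    minimum-mean site, provided it excludes the maximum-mean site's group
    (and vice versa for the high tail); when the letter display cannot
    separate the tails it falls back to ``k_extremes`` (k lowest / highest
    site means) with a logged notice.
    """
    import logging

    block = per_year[(per_year["scope"] == scope) & (per_year["parameter"] == parameter)]
    if block.empty:
        raise ValueError(f"no data for parameter {parameter!r} in scope {scope!r}")
    means = block.groupby("site_id")["value"].mean().sort_values()
    if means.nunique() == 1:
        raise ValueError("no extreme contrast: all site means equal")
    if method == "tukey_tails":
        res = group_stat_anova(block["value"].values, block["site_id"].values, alpha)
        lo_site, hi_site = means.index[0], means.index[-1]
        lo_letters = set(res.letters[lo_site])
        hi_letters = set(res.letters[hi_site])
        low = tuple(
            s for s in means.index
            if set(res.letters[s]) & lo_letters and not set(res.letters[s]) & hi_letters
        )
        high = tuple(
            s for s in means.index
            if set(res.letters[s]) & hi_letters and not set(res.letters[s]) & lo_letters
        )
        if low and high and not (set(low) & set(high)):
            return ExtremeGroups(
                parameter=parameter, scope=scope, low_sites=low, high_sites=high,
                method="tukey_tails", alpha=alpha,
            )
        logging.getLogger(__name__).info(
            "tukey_tails could not separate extremes for %s; falling back to "
            "k_extremes with k=%d", parameter, k,
        )
        method = "k_extremes"
    if method == "k_extremes":
        low = tuple(means.index[:k])
        high = tuple(means.index[-k:])
        if set(low) & set(high):
            raise ValueError("no extreme contrast: k overlaps both tails")
        return ExtremeGroups(
            parameter=parameter, scope=scope, low_sites=low, high_sites=high,
            method="k_extremes", k=k,
        )
    raise ValueError(f"unknown method {method!r}")
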