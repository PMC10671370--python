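"""Diversity statistics, mutation spectrum and sliding-window summaries.

For pooled accessions the "observed heterozygosity" Ho is the fraction of
loci at which the pool shows both alleles; in a predominantly selfing crop
genotyped as seedling pools this is read as accession *heterogeneity*
(how many distinct genotypes the pool contains) rather than individual
heterozygosity.  uHe is Nei's unbiased gene diversity with the 2n/(2n-1)
small-sample correction, and the fixation index is F = 1 - Ho/uHe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NUCLEOTIDES, VALID_CHROMS, GenotypeMatrix, allele_frequency_alt

#: ordered substitution types (4 transitions first, then 8 transversions)
SUBSTITUTION_TYPES = (
    "A>G", "G>A", "C>T", "T>C",           # transitions
    "A>C", "A>T", "G>C", "G>T",           # transversions
    "C>A", "C>G", "T>A", "T>G",
)
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


def allele_frequencies(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus (p_ref, p_alt, n_non_missing); all-missing loci get NaN."""
    p_alt = allele_frequency_alt(gm)
    n = gm.calls.notna().sum(axis=0)
    return pd.DataFrame({"p_ref": 1.0 - p_alt, "p_alt": p_alt, "n_non_missing": n})


def pic(p_alt) -> np.ndarray | float:
    """Botstein polymorphism information content for a biallelic locus.

    ``PIC = 1 - (p^2 + q^2) - 2 p^2 q^2``; its maximum for two alleles is
    0.375 at p = 0.5.
    """
    p = np.asarray(p_alt, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return out if out.ndim else float(out)


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus frequency, PIC, observed-het fraction and unbiased He."""
    freqs = allele_frequencies(gm)
    calls = gm.calls
    n = freqs["n_non_missing"]
    ho = (calls == 1.0).sum(axis=0) / n.where(n > 0)
    p, q = freqs["p_alt"], freqs["p_ref"]
    he = 1.0 - (p**2 + q**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        uhe = (2.0 * n / (2.0 * n - 1.0)).where(n > 1) * he
    return pd.DataFrame(
        {
            "p_ref": q, "p_alt": p, "n_non_missing": n,
            "pic": pic(p.values), "ho_locus": ho, "uhe_locus": uhe,
        }
    )


def accession_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-accession fraction of heterozygous (both-alleles) loci."""
    calls = gm.calls
    n_called = calls.notna().sum(axis=1)
    ho = (calls == 1.0).sum(axis=1) / n_called.where(n_called > 0)
    return pd.DataFrame({"ho_accession": ho, "n_loci_called": n_called})


@dataclass(frozen=True)
class DiversitySummary:
    """Group-level mean diversity coefficients."""

    group: str
    ho: float
    uhe: float
    f: float          # NaN when uHe is 0 or undefined
    n_accessions: int
    n_loci: int


def diversity_summary(
    gm: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    by_chromosome: bool = False,
) -> list[DiversitySummary]:
    """Mean Ho / uHe / F per accession group (optionally per chromosome).

    *grouping* maps accession id -> group label; ``None`` treats the whole
    collection as one group labelled ``"all"``.  Groups of size 1 report
    uHe (and hence F) as NaN.
    """
    if grouping is None:
        grouping = {a: "all" for a in gm.accession_ids}
    unknown = set(grouping) - set(gm.accession_ids)
    if unknown:
        raise ValueError(f"grouping names unknown accessions: {sorted(unknown)}")
    out: list[DiversitySummary] = []
    groups: dict[str, list[str]] = {}
    for acc, g in grouping.items():
        groups.setdefault(g, []).append(acc)
    for label in sorted(groups):
        sub = gm.subset_accessions(groups[label])
        if by_chromosome:
            for chrom in VALID_CHROMS:
                lids = sub.loci.index[sub.loci["chrom"] == chrom]
                if len(lids) == 0:
                    continue
                out.append(_summarize(sub.subset_loci(lids), f"{label}:{chrom}"))
        else:
            out.append(_summarize(sub, label))
    return out


def _summarize(gm: GenotypeMatrix, label: str) -> DiversitySummary:
    st = locus_stats(gm)
    informative = st["n_non_missing"] > 0
    ho = float(st.loc[informative, "ho_locus"].mean())
    uhe = float(st["uhe_locus"].mean()) if st["uhe_locus"].notna().any() else np.nan
    f = 1.0 - ho / uhe if uhe and not np.isnan(uhe) and uhe > 0 else np.nan
    return DiversitySummary(
        group=label, ho=ho, uhe=uhe, f=f,
        n_accessions=gm.n_accessions, n_loci=gm.n_loci,
    )


# ---------------------------------------------------------------------------
# mutation spectrum
# ---------------------------------------------------------------------------

def mutation_spectrum(loci: pd.DataFrame) -> pd.DataFrame:
    """Classify loci by ordered ref>alt substitution per chromosome.

    Returns a table with one row per substitution type plus ``%Ts``,
    ``%Tv`` and ``Ts/Tv`` rows, one column per chromosome plus ``Total``.
    Loci with non-ACGT alleles or unknown chromosome are excluded (their
    number is available via the difference from ``len(loci)``).
    """
    ok = (
        loci["ref_allele"].isin(NUCLEOTIDES)
        & loci["alt_allele"].isin(NUCLEOTIDES)
        & loci["chrom"].isin(VALID_CHROMS)
    )
    sub = loci[ok]
    types = sub["ref_allele"] + ">" + sub["alt_allele"]
    counts = pd.DataFrame(
        0, index=list(SUBSTITUTION_TYPES), columns=list(VALID_CHROMS) + ["Total"]
    )
    tab = pd.crosstab(types, sub["chrom"])
    for t in tab.index:
        for c in tab.columns:
            counts.loc[t, c] = tab.loc[t, c]
    counts["Total"] = counts[list(VALID_CHROMS)].sum(axis=1)

    ts_rows = [t for t in SUBSTITUTION_TYPES if t in TRANSITIONS]
    tv_rows = [t for t in SUBSTITUTION_TYPES if t not in TRANSITIONS]
    ts = counts.loc[ts_rows].sum()
    tv = counts.loc[tv_rows].sum()
    total = ts + tv
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_ts = 100.0 * ts / total
        pct_tv = 100.0 * tv / total
        ratio = ts / tv
    counts.loc["%Ts"] = pct_ts
    counts.loc["%Tv"] = pct_tv
    counts.loc["Ts/Tv"] = ratio
    return counts


def spectrum_to_loci(counts: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Expand a per-chromosome substitution count table into a locus table.

    The inverse of the counting step in :func:`mutation_spectrum`: given a
    12 x 7 table of counts it materializes one locus row per counted
    substitution (positions arbitrary).  Used to re-analyze published
    spectrum tables through the same code path as raw loci.
    """
    rows = []
    i = 0
    for t in SUBSTITUTION_TYPES:
        ref, alt = t.split(">")
        for chrom in VALID_CHROMS:
            n = int(counts.loc[t, chrom])
            for _ in range(n):
                i += 1
                rows.append(
                    {
                        "locus_id": f"L{i:06d}", "chrom": chrom, "pos_bp": i,
                        "ref_allele": ref, "alt_allele": alt,
                        "rep_avg": 1.0, "call_rate": 1.0,
                    }
                )
    return pd.DataFrame(rows).set_index("locus_id")


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowProfile:
    """Equally spaced overlapping-window track along one chromosome."""

    chrom: str
    centers: np.ndarray      # bp, strictly increasing
    half_width_bp: int
    values: np.ndarray       # count or mean statistic per window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "center_bp": self.centers,
                "start_bp": np.maximum(1, self.centers - self.half_width_bp),
                "end_bp": self.centers + self.half_width_bp,
                "value": self.values,
            }
        )


def sliding_window_profile(
    loci: pd.DataFrame,
    chrom_lengths: dict[str, int],
    values: pd.Series | None = None,
    n_positions: int = 250,
    half_width_bp: int = 250_000,
) -> dict[str, WindowProfile]:
    """Windowed locus count (or mean of *values*) along each chromosome.

    Window centers sit at ``k L / (n_positions + 1)`` for k = 1..n_positions;
    each window is the closed interval ``[center - half_width,
    center + half_width]`` clipped to ``[1, L]``, so adjacent windows
    overlap and a locus on a shared boundary is counted in both.
    """
    profiles: dict[str, WindowProfile] = {}
    for chrom, length in chrom_lengths.items():
        if length is None or length <= 0:
            raise ValueError(f"no length for chromosome {chrom}")
        k = np.arange(1, n_positions + 1)
        centers = k * length / (n_positions + 1)
        on_chrom = loci[loci["chrom"] == chrom]
        pos = on_chrom["pos_bp"].to_numpy(float)
        lo = np.maximum(1.0, centers - half_width_bp)
        hi = np.minimum(float(length), centers + half_width_bp)
        inside = (pos[None, :] >= lo[:, None]) & (pos[None, :] <= hi[:, None])
        if values is None:
            vals = inside.sum(axis=1).astype(float)
        else:
            v = values.reindex(on_chrom.index).to_numpy(float)
            with np.errstate(invalid="ignore"):
                vals = np.where(
                    inside.any(axis=1),
                    np.nansum(np.where(inside, v[None, :], np.nan), axis=1)
                    / inside.sum(axis=1),
                    0.0,
                )
        profiles[chrom] = WindowProfile(
            chrom=chrom, centers=centers, half_width_bp=half_width_bp, values=vals
        )
    return profiles


# ---------------------------------------------------------------------------
# one-way ANOVA with Tukey HSD letters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    tukey: pd.DataFrame          # pairwise table: group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]      # homogeneous-group letters per group


def group_stat_anova(values, groups, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA plus Tukey HSD with homogeneous-group letters.

    Tukey adjusted p-values come from the studentized-range distribution.
    With zero within-group variance and equal means the F statistic is
    undefined and reported as NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 observations per group")

    n_total = len(values)
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = len(labels) - 1, n_total - len(labels)
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f_stat = np.nan if ss_between == 0.0 else np.inf
        p = np.nan if ss_between == 0.0 else 0.0
    else:
        f_stat = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))

    means = {g: float(s.mean()) for g, s in zip(labels, samples)}
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            ni, nj = len(samples[i]), len(samples[j])
            diff = means[gj] - means[gi]
            if ms_w > 0:
                se = np.sqrt(ms_w / 2.0 * (1.0 / ni + 1.0 / nj))
                q_obs = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q_obs, len(labels), df_w))
            else:
                p_adj = np.nan if diff == 0 else 0.0
            rows.append(
                {
                    "group1": gi, "group2": gj, "meandiff": diff,
                    "p_adj": p_adj, "reject": bool(p_adj < alpha),
                }
            )
    tukey = pd.DataFrame(rows)
    letters = _homogeneous_letters(labels, means, tukey)
    return AnovaResult(
        f_statistic=float(f_stat), p_value=p, group_means=means,
        tukey=tukey, letters=letters,
    )


def _homogeneous_letters(labels, means, tukey: pd.DataFrame) -> dict[str, str]:
    """Insert-and-absorb letter display: groups sharing a letter do not differ."""
    order = sorted(labels, key=lambda g: means[g])
    differ = {
        frozenset((r.group1, r.group2)) for r in tukey.itertuples() if r.reject
    }
    cliques: list[set] = []
    for g in order:
        placed = False
        for clique in cliques:
            if all(frozenset((g, h)) not in differ for h in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb cliques fully contained in another
    cliques = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for letter, clique in zip(alphabet, cliques):
        for g in sorted(clique, key=lambda g: means[g]):
            letters[g] += letter
    return letters
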