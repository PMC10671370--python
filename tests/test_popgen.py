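"""Diversity coefficients, substitution spectrum, windows, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dartpool import (
    accession_heterozygosity,
    allele_frequencies,
    diversity_summary,
    group_stat_anova,
    load_reference_spectrum,
    locus_stats,
    mutation_spectrum,
    pic,
    sliding_window_profile,
    spectrum_to_loci,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# frequencies and PIC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "calls,expected_p_alt",
    [
        ([[0], [0], [2], [2]], 0.5),          # symmetry
        ([[0], [1], [1], [2]], 0.5),          # (1+1+2)/8
        ([[0], [0], [0], [1]], 0.125),        # 1/8
    ],
)
def test_allele_frequency_hand_counts(calls, expected_p_alt):
    freqs = allele_frequencies(toy_matrix(calls))
    assert freqs["p_alt"].iloc[0] == pytest.approx(expected_p_alt)
    assert freqs["p_ref"].iloc[0] == pytest.approx(1 - expected_p_alt)


@pytest.mark.parametrize(
    "p,expected",
    [(0.0, 0.0), (0.5, 0.375), (0.1, 0.1638), (1.0, 0.0)],
)
def test_pic_known_values(p, expected):
    assert pic(p) == pytest.approx(expected, abs=1e-10)


def test_pic_bounded_by_expected_heterozygosity():
    p = np.linspace(0, 1, 201)
    he = 1 - p**2 - (1 - p) ** 2
    vals = pic(p)
    assert np.all(vals <= he + 1e-12)
    interior = (p > 0) & (p < 1)
    assert np.all(vals[interior] < he[interior])
    assert np.max(vals) == pytest.approx(0.375)


# ---------------------------------------------------------------------------
# diversity summaries
# ---------------------------------------------------------------------------

def test_diversity_all_hom_ref():
    summary = diversity_summary(toy_matrix([[0, 0], [0, 0]]))[0]
    assert summary.ho == 0.0
    assert summary.uhe == 0.0
    assert np.isnan(summary.f)


def test_diversity_two_accessions_hand_computation():
    # calls (0, 2): Ho 0, uHe = (4/3) * 0.5 = 0.6667, F = 1
    summary = diversity_summary(toy_matrix([[0], [2]]))[0]
    assert summary.ho == 0.0
    assert summary.uhe == pytest.approx(2 / 3)
    assert summary.f == pytest.approx(1.0)


def test_fixation_index_identity_at_published_coefficients():
    # the implemented definition F = 1 - Ho/uHe must reconcile the
    # printed collection-level coefficients within rounding
    ho, uhe = 0.242, 0.443
    f = 1 - ho / uhe
    assert f == pytest.approx(0.454, abs=0.002)
    assert round(f, 2) == pytest.approx(0.45)


def test_group_of_size_one_reports_missing_uhe():
    gm = toy_matrix([[0, 1], [2, 1], [0, 0]])
    res = diversity_summary(gm, {"A1": "g1", "A2": "g1", "A3": "solo"})
    solo = next(s for s in res if s.group == "solo")
    assert np.isnan(solo.uhe) and np.isnan(solo.f)


def test_accession_heterozygosity_counts_both_allele_calls():
    gm = toy_matrix([[1, 1, 0, 2], [0, 0, 0, np.nan]])
    ho = accession_heterozygosity(gm)
    assert ho.loc["A1", "ho_accession"] == pytest.approx(0.5)
    assert ho.loc["A2", "ho_accession"] == 0.0
    assert ho.loc["A2", "n_loci_called"] == 3


def test_pooled_union_uhe_not_below_subgroup_mean():
    # mixing two groups fixed for different alleles raises expected
    # heterozygosity above the within-group values (Wahlund direction)
    gm = toy_matrix([[0], [0], [2], [2]])
    union = diversity_summary(gm)[0]
    split = diversity_summary(gm, {"A1": "a", "A2": "a", "A3": "b", "A4": "b"})
    assert union.uhe > max(s.uhe for s in split)


# ---------------------------------------------------------------------------
# mutation spectrum
# ---------------------------------------------------------------------------

def test_spectrum_classifies_definitions():
    loci = pd.DataFrame(
        {
            "chrom": ["1H", "1H"], "pos_bp": [1, 2],
            "ref_allele": ["A", "G"], "alt_allele": ["G", "C"],
        },
        index=["L1", "L2"],
    )
    tab = mutation_spectrum(loci)
    assert tab.loc["A>G", "1H"] == 1      # transition
    assert tab.loc["G>C", "1H"] == 1      # transversion
    assert tab.loc["%Ts", "1H"] == pytest.approx(50.0)


def test_spectrum_reference_table_recomputed():
    # expanding the published count table to loci and re-counting must
    # reproduce the published summary statistics
    counts = load_reference_spectrum()
    loci = spectrum_to_loci(counts)
    tab = mutation_spectrum(loci)
    ts = tab.loc[["A>G", "G>A", "C>T", "T>C"], "Total"].sum()
    tv = tab.iloc[:12]["Total"].sum() - ts
    assert (ts, tv) == (5815, 3922)
    assert tab.loc["Ts/Tv", "Total"] == pytest.approx(1.48, abs=0.005)
    assert tab.loc["Ts/Tv", "1H"] == pytest.approx(1.59, abs=0.005)
    assert tab.loc["%Ts", "5H"] == pytest.approx(61.5, abs=0.05)


def test_spectrum_counts_sum_and_nonacgt_excluded(collection):
    loci = collection.genotypes.loci
    tab = mutation_spectrum(loci)
    assert tab.iloc[:12]["Total"].sum() == len(loci)
    # per-chromosome columns sum to totals
    np.testing.assert_array_equal(
        tab.iloc[:12][[f"{i}H" for i in range(1, 8)]].sum(axis=1).values,
        tab.iloc[:12]["Total"].values,
    )


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def test_window_all_loci_in_one_window():
    loci = pd.DataFrame(
        {"chrom": ["1H"] * 10, "pos_bp": np.arange(500_000, 500_010)},
        index=[f"L{i}" for i in range(10)],
    )
    prof = sliding_window_profile(loci, {"1H": 100_000_000})["1H"]
    nearest = np.argmin(np.abs(prof.centers - 500_005))
    assert prof.values[nearest] == 10


def test_window_empty_chromosome_all_zero():
    loci = pd.DataFrame({"chrom": [], "pos_bp": []})
    prof = sliding_window_profile(loci, {"2H": 1_000_000})["2H"]
    assert (prof.values == 0).all()
    assert np.all(np.diff(prof.centers) > 0)


def test_window_boundary_locus_counted_in_both_windows():
    # choose L so adjacent window intervals share an integer boundary:
    # centers at k*L/(n+1) with spacing L/(n+1); a locus on the shared
    # closed boundary belongs to both windows
    n, hw = 250, 250_000
    length = (n + 1) * hw * 2          # spacing = 2*hw -> windows touch
    k = 100
    boundary = int(k * length / (n + 1) + hw)
    loci = pd.DataFrame({"chrom": ["3H"], "pos_bp": [boundary]}, index=["L1"])
    prof = sliding_window_profile(loci, {"3H": length}, n_positions=n,
                                  half_width_bp=hw)["3H"]
    assert prof.values[k - 1] == 1 and prof.values[k] == 1
    assert prof.values.sum() == 2


def test_window_requires_length():
    loci = pd.DataFrame({"chrom": ["1H"], "pos_bp": [5]}, index=["L1"])
    with pytest.raises(ValueError, match="length"):
        sliding_window_profile(loci, {"1H": 0})


# ---------------------------------------------------------------------------
# ANOVA and Tukey letters
# ---------------------------------------------------------------------------

def test_anova_identical_groups_f_near_zero():
    vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    res = group_stat_anova(vals, ["a", "a", "a", "b", "b", "b"])
    assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.99


def test_anova_two_separated_groups_hand_value():
    res = group_stat_anova([1, 2, 3, 11, 12, 13], ["a"] * 3 + ["b"] * 3)
    assert res.f_statistic == pytest.approx(150.0)
    assert res.p_value < 0.001
    # two-group Tukey p equals the ANOVA p
    assert res.tukey["reject"].all()


def test_tukey_flags_only_pairs_involving_the_outlier_group():
    rng = np.random.default_rng(0)
    vals = np.concatenate([
        rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(8, 1, 10)
    ])
    groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    res = group_stat_anova(vals, groups)
    flagged = {
        frozenset((r.group1, r.group2)) for r in res.tukey.itertuples() if r.reject
    }
    assert flagged == {frozenset(("a", "c")), frozenset(("b", "c"))}
    assert res.letters["a"] == res.letters["b"] != res.letters["c"]


def test_tukey_matches_statsmodels_reference():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(7)
    vals = np.concatenate(
        [rng.normal(m, 1.2, 8) for m in (0.0, 1.5, 4.0)]
    )
    groups = np.repeat(["a", "b", "c"], 8)
    res = group_stat_anova(vals, groups)
    ref = pairwise_tukeyhsd(vals, groups, alpha=0.05)
    ref_p = {
        frozenset((g1, g2)): p
        for (g1, g2), p in zip(
            [(str(r[0]), str(r[1])) for r in ref.summary().data[1:]],
            ref.pvalues,
        )
    }
    for r in res.tukey.itertuples():
        assert r.p_adj == pytest.approx(ref_p[frozenset((r.group1, r.group2))],
                                        abs=1e-6)


def test_tukey_p_matches_studentized_range_oracle():
    # direct studentized-range computation as the independent oracle
    vals = np.array([1.0, 1.5, 2.0, 4.0, 4.5, 5.0, 9.0, 9.5, 10.0])
    groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    res = group_stat_anova(vals, groups)
    labels = ["a", "b", "c"]
    samples = {g: vals[groups == g] for g in labels}
    ms_w = np.mean([samples[g].var(ddof=1) for g in labels])
    for r in res.tukey.itertuples():
        q = abs(samples[r.group2].mean() - samples[r.group1].mean()) / np.sqrt(ms_w / 3)
        expected = stats.studentized_range.sf(q, 3, 6)
        assert r.p_adj == pytest.approx(expected, rel=1e-10)
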