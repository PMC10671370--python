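"""Extreme-environment unique-allele detection, dedup, windows, genes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dartpool import (
    cluster_records,
    dedupe_union,
    detect_unique_alleles,
    expected_detector_output,
    genes_near,
    unique_window_profile,
)
from dartpool.ecogeo import ExtremeGroups
from dartpool.io import GeneAnnotation
from dartpool.unique_alleles import UniqueAlleleRecord, UniqueAlleleSet

from conftest import toy_matrix


def _groups(low=("A1",), high=("A4",), parameter="PDSI"):
    return ExtremeGroups(
        parameter=parameter, scope="annual", low_sites=tuple(low),
        high_sites=tuple(high), method="k_extremes", k=1,
    )


def test_alt_unique_to_single_high_accession():
    gm = toy_matrix([[0], [0], [0], [1]])
    recs = detect_unique_alleles(gm, _groups(), background=list("A1 A2 A3 A4".split()))
    found = [(r.allele, r.direction) for r in recs]
    assert ("alt", "high") in found
    assert all(d != "low" or a != "alt" for a, d in found)


def test_allele_shared_outside_group_not_unique():
    gm = toy_matrix([[0], [1], [0], [1]])   # A2 (outside) also carries alt
    recs = detect_unique_alleles(gm, _groups(), background=["A1", "A2", "A3", "A4"])
    assert not any(r.allele == "alt" for r in recs)


def test_missing_policy_branches():
    # alt carried in-group; one outside accession missing at that locus
    gm = toy_matrix([[0], [np.nan], [0], [1]])
    background = ["A1", "A2", "A3", "A4"]
    strict = detect_unique_alleles(gm, _groups(), background, missing_policy="strict")
    lenient = detect_unique_alleles(gm, _groups(), background, missing_policy="lenient")
    assert not any(r.allele == "alt" for r in strict)
    assert any(r.allele == "alt" and r.direction == "high" for r in lenient)


def test_empty_group_errors():
    gm = toy_matrix([[0], [1]])
    with pytest.raises(ValueError, match="empty extreme group"):
        detect_unique_alleles(gm, _groups(low=("absent",), high=("A2",)),
                              background=["A1", "A2"])


def _brute_force(gm, members, outside, policy):
    """Oracle: direct scan over (locus, allele) with explicit set logic."""
    out = set()
    for lid in gm.locus_ids:
        col = gm.calls[lid]
        for allele, codes in (("ref", {0.0, 1.0}), ("alt", {1.0, 2.0})):
            in_carry = any(col[a] in codes for a in members if not np.isnan(col[a]))
            out_carry = any(col[a] in codes for a in outside if not np.isnan(col[a]))
            out_missing = any(np.isnan(col[a]) for a in outside)
            ok = in_carry and not out_carry
            if policy == "strict" and out_missing:
                ok = False
            if ok:
                out.add((lid, allele))
    return out


@pytest.mark.parametrize("policy", ["strict", "lenient"])
def test_detection_matches_brute_force_oracle(policy):
    rng = np.random.default_rng(9)
    codes = rng.choice([0.0, 1.0, 2.0, np.nan], size=(16, 150),
                       p=[0.55, 0.2, 0.2, 0.05])
    gm = toy_matrix(codes)
    accs = gm.accession_ids
    members = accs[:3]
    background = accs
    grp = ExtremeGroups(parameter="soil", scope="annual",
                        low_sites=tuple(members), high_sites=(accs[3],),
                        method="k_extremes", k=1)
    recs = detect_unique_alleles(gm, grp, background, missing_policy=policy)
    got_low = {(r.locus_id, r.allele) for r in recs if r.direction == "low"}
    want_low = _brute_force(gm, members, [a for a in accs if a not in members], policy)
    assert got_low == want_low


def test_background_monotonicity():
    # enlarging the background can only shrink (or keep) the unique set
    rng = np.random.default_rng(10)
    codes = rng.choice([0.0, 1.0, 2.0], size=(12, 80), p=[0.6, 0.2, 0.2])
    gm = toy_matrix(codes)
    accs = gm.accession_ids
    grp = ExtremeGroups(parameter="ppt", scope="annual",
                        low_sites=(accs[0],), high_sites=(accs[1],),
                        method="k_extremes", k=1)
    small = detect_unique_alleles(gm, grp, accs[:8])
    large = detect_unique_alleles(gm, grp, accs)
    as_set = lambda rs: {(r.locus_id, r.allele, r.direction) for r in rs}
    assert as_set(large) <= as_set(small)


def test_dedupe_arithmetic_and_idempotence():
    def rec(lid, param):
        return UniqueAlleleRecord(lid, "alt", param, "low", ("A1",), "1H", 1)

    soil = [rec("L1", "soil"), rec("L2", "soil")]
    ppt = [rec("L1", "ppt"), rec("L3", "ppt")]
    uset = dedupe_union([soil, ppt])
    assert uset.multiplicity_count == 4
    assert uset.dedup_count == 3
    again = dedupe_union([uset.records])
    assert again.dedup_count == uset.dedup_count
    reordered = dedupe_union([ppt, soil])
    assert set(reordered.deduplicated) == set(uset.deduplicated)
    assert uset.per_parameter_counts().to_dict() == {"ppt": 2, "soil": 2}


def test_planted_alleles_recovered_exactly(clean_collection):
    coll = clean_collection
    truth = coll.manifest.extreme_sites["PDSI"]
    grp = ExtremeGroups(parameter="PDSI", scope="annual",
                        low_sites=tuple(truth["low"]),
                        high_sites=tuple(truth["high"]),
                        method="k_extremes", k=2)
    background = [a for a, s in coll.status.items() if s == "landrace"]
    recs = detect_unique_alleles(coll.genotypes, grp, background,
                                 coll.site_of_accession, "strict")
    got = {(r.locus_id, r.allele, r.direction) for r in recs}
    expected = expected_detector_output(coll.manifest)
    want = {(r.locus_id, r.allele, r.direction) for r in expected.records}
    assert got == want          # recall 1.0 and precision 1.0


def test_unique_window_profile_counts_dedup(clean_collection):
    uset = expected_detector_output(clean_collection.manifest)
    # enough window positions that the 500-kb windows tile the chromosome:
    # every record is covered, and overlap can only double-count
    profiles = unique_window_profile(
        uset, {"5H": 670_030_000, "6H": 583_380_000}, n_positions=1400
    )
    total_in_windows = sum(p.values.sum() for p in profiles.values())
    assert total_in_windows >= uset.dedup_count
    assert all((p.values >= 0).all() for p in profiles.values())


def test_cluster_records_gap_rule():
    recs = [
        UniqueAlleleRecord(f"L{i}", "alt", "PDSI", "low", ("A1",), "6H", pos)
        for i, pos in enumerate([100, 200, 5_000_000, 5_000_100])
    ]
    clusters = cluster_records(UniqueAlleleSet(recs), cluster_gap_bp=1_000_000)
    assert len(clusters) == 2
    assert (clusters[0].start_bp, clusters[0].end_bp) == (100, 200)
    assert clusters[1].n_records == 2


def test_genes_near_containment_and_distance():
    clusters = cluster_records(
        UniqueAlleleSet([
            UniqueAlleleRecord("L1", "alt", "PDSI", "low", ("A1",), "6H", 19_490_420),
            UniqueAlleleRecord("L2", "alt", "PDSI", "low", ("A1",), "6H", 19_611_998),
        ]),
        cluster_gap_bp=2_000_000,
    )
    genes = [
        GeneAnnotation("Gin", "6H", 19_500_000, 19_505_000, "inside"),
        GeneAnnotation("Gnear", "6H", 19_621_998, 19_630_000, "10 kb past end"),
        GeneAnnotation("Gfar", "6H", 25_000_000, 25_010_000, "too far"),
        GeneAnnotation("Gother", "5H", 19_500_000, 19_505_000, "wrong chrom"),
    ]
    report = genes_near(clusters, genes, max_gap_bp=50_000)
    assert report["gene_id"].tolist() == ["Gin", "Gnear"]
    assert report.set_index("gene_id").loc["Gin", "distance_bp"] == 0
    assert report.set_index("gene_id").loc["Gnear", "distance_bp"] == 10_000
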