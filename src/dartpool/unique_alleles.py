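"""Detection of alleles unique to accessions from extreme-environment sites.

An allele (ref or alt) at a locus is *unique* to an extreme group when at
least one group member carries it (pooled code 1 counts as carrying both
alleles) and no background accession outside the group shows it in any
non-missing call.  Under the ``strict`` missing policy any missing call
outside the group disqualifies the locus (the allele could be hiding
there); ``lenient`` treats missing as absent.  Records are collected per
(parameter, direction) contrast, deduplicated on (locus, allele) across
parameters, localized with sliding-window profiles, and annotated with
neighboring genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecogeo import ExtremeGroups
from .io import GeneAnnotation, GenotypeMatrix
from .popgen import WindowProfile, sliding_window_profile


@dataclass(frozen=True)
class UniqueAlleleRecord:
    locus_id: str
    allele: str          # "ref" | "alt"
    parameter: str
    direction: str       # "low" | "high"
    carriers: tuple[str, ...]
    chrom: str
    pos_bp: int


@dataclass
class UniqueAlleleSet:
    """Per-parameter records plus the deduplicated (locus, allele) view."""

    records: list[UniqueAlleleRecord]

    @property
    def multiplicity_count(self) -> int:
        return len(self.records)

    @property
    def deduplicated(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for r in self.records:
            seen.setdefault((r.locus_id, r.allele))
        return list(seen)

    @property
    def dedup_count(self) -> int:
        return len(self.deduplicated)

    def per_parameter_counts(self) -> pd.Series:
        return pd.Series(
            [r.parameter for r in self.records], dtype=object
        ).value_counts().sort_index()

    def per_chromosome_counts(self) -> pd.Series:
        dedup_chrom = {}
        for r in self.records:
            dedup_chrom.setdefault((r.locus_id, r.allele), r.chrom)
        return pd.Series(list(dedup_chrom.values()), dtype=object).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": r.locus_id, "allele": r.allele,
                    "parameter": r.parameter, "direction": r.direction,
                    "carriers": ";".join(r.carriers),
                    "chrom": r.chrom, "pos_bp": r.pos_bp,
                }
                for r in self.records
            ]
        )


def detect_unique_alleles(
    gm: GenotypeMatrix,
    groups: ExtremeGroups,
    background: list[str],
    site_of_accession: dict[str, str] | None = None,
    missing_policy: str = "strict",
) -> list[UniqueAlleleRecord]:
    """Find alleles carried only inside an extreme group.

    *background* lists the accessions forming the comparison universe
    (typically all landraces with eco-geographical data); the extreme-group
    accessions must be a subset of it.  *site_of_accession* maps accession
    id -> site id; if omitted, group site ids are taken as accession ids
    directly.
    """
    if missing_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    site_of = site_of_accession or {a: a for a in background}
    records: list[UniqueAlleleRecord] = []
    for direction, sites in (("low", groups.low_sites), ("high", groups.high_sites)):
        members = [a for a in background if site_of.get(a) in set(sites)]
        if not members:
            raise ValueError(f"empty extreme group ({groups.parameter}, {direction})")
        outside = [a for a in background if a not in set(members)]
        records.extend(
            _detect_one_group(gm, members, outside, groups.parameter, direction,
                              missing_policy)
        )
    return records


def _detect_one_group(
    gm: GenotypeMatrix,
    members: list[str],
    outside: list[str],
    parameter: str,
    direction: str,
    missing_policy: str,
) -> list[UniqueAlleleRecord]:
    calls_in = gm.calls.loc[members]
    calls_out = gm.calls.loc[outside]

    present_in = {
        "ref": calls_in.isin([0.0, 1.0]),
        "alt": calls_in.isin([1.0, 2.0]),
    }
    present_out = {
        "ref": calls_out.isin([0.0, 1.0]).any(axis=0),
        "alt": calls_out.isin([1.0, 2.0]).any(axis=0),
    }
    out_has_missing = calls_out.isna().any(axis=0)

    records = []
    for allele in ("ref", "alt"):
        carried = present_in[allele].any(axis=0)
        absent_outside = ~present_out[allele]
        if missing_policy == "strict":
            absent_outside &= ~out_has_missing
        unique = carried & absent_outside
        for lid in gm.calls.columns[unique]:
            carriers = tuple(calls_in.index[present_in[allele][lid]])
            meta = gm.loci.loc[lid]
            records.append(
                UniqueAlleleRecord(
                    locus_id=lid, allele=allele, parameter=parameter,
                    direction=direction, carriers=carriers,
                    chrom=str(meta["chrom"]), pos_bp=int(meta["pos_bp"]),
                )
            )
    return records


def dedupe_union(per_parameter_records: list[list[UniqueAlleleRecord]]) -> UniqueAlleleSet:
    """Union of per-parameter record lists with the deduplicated view.

    Multiplicity counts every (parameter, direction) record; deduplication
    is on (locus_id, allele).  Idempotent and order-invariant in its
    dedup view.
    """
    all_records = [r for sub in per_parameter_records for r in sub]
    return UniqueAlleleSet(records=all_records)


def unique_window_profile(
    uset: UniqueAlleleSet,
    chrom_lengths: dict[str, int],
    parameter: str | None = None,
    n_positions: int = 250,
    half_width_bp: int = 250_000,
) -> dict[str, WindowProfile]:
    """Sliding-window counts of unique records (optionally one parameter)."""
    recs = uset.records
    if parameter is not None:
        recs = [r for r in recs if r.parameter == parameter]
    # dedup on (locus, allele) so a shared allele is one mark on the track
    seen = {}
    for r in recs:
        seen.setdefault((r.locus_id, r.allele), r)
    loci = pd.DataFrame(
        {
            "chrom": [r.chrom for r in seen.values()],
            "pos_bp": [r.pos_bp for r in seen.values()],
        },
        index=[f"{lid}:{al}" for lid, al in seen],
    )
    return sliding_window_profile(
        loci, chrom_lengths, n_positions=n_positions, half_width_bp=half_width_bp
    )


@dataclass(frozen=True)
class RecordCluster:
    chrom: str
    start_bp: int
    end_bp: int
    n_records: int


def cluster_records(
    uset: UniqueAlleleSet, cluster_gap_bp: int = 2_000_000
) -> list[RecordCluster]:
    """Maximal runs of unique records with inter-record gap <= cluster_gap_bp."""
    dedup = {}
    for r in uset.records:
        dedup.setdefault((r.locus_id, r.allele), (r.chrom, r.pos_bp))
    clusters: list[RecordCluster] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in dedup.values():
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        n = 1
        for pos in positions[1:]:
            if pos - prev <= cluster_gap_bp:
                prev = pos
                n += 1
            else:
                clusters.append(RecordCluster(chrom, start, prev, n))
                start = prev = pos
                n = 1
        clusters.append(RecordCluster(chrom, start, prev, n))
    return clusters


def genes_near(
    clusters: list[RecordCluster],
    annotation: list[GeneAnnotation],
    max_gap_bp: int = 500_000,
) -> pd.DataFrame:
    """Genes overlapping each cluster extended by max_gap_bp on both sides.

    Distance is 0 for genes overlapping the (unextended) cluster interval,
    otherwise the gap to the nearest cluster edge.  Output is ordered by
    chromosome then gene start.
    """
    rows = []
    known_chroms = {c.chrom for c in clusters}
    for gene in annotation:
        if gene.chrom not in known_chroms:
            continue
        for cl in clusters:
            if cl.chrom != gene.chrom:
                continue
            lo, hi = cl.start_bp - max_gap_bp, cl.end_bp + max_gap_bp
            if gene.end_bp < lo or gene.start_bp > hi:
                continue
            if gene.end_bp >= cl.start_bp and gene.start_bp <= cl.end_bp:
                distance = 0
            elif gene.end_bp < cl.start_bp:
                distance = cl.start_bp - gene.end_bp
            else:
                distance = gene.start_bp - cl.end_bp
            rows.append(
                {
                    "chrom": gene.chrom,
                    "cluster_start": cl.start_bp, "cluster_end": cl.end_bp,
                    "gene_id": gene.gene_id, "gene_start": gene.start_bp,
                    "gene_end": gene.end_bp, "distance_bp": distance,
                    "description": gene.description,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "cluster_start", "cluster_end", "gene_id", "gene_start",
            "gene_end", "distance_bp", "description",
        ],
    )
    return df.sort_values(["chrom", "gene_start"], kind="stable").reset_index(drop=True)
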