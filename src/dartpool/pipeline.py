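"""End-to-end orchestration of the analysis stages with a run report.

The pipeline runs, in order: quality filtering -> diversity coefficients ->
substitution spectrum -> Jaccard distance -> PCoA -> AMOVA -> Mantel tests
against geographic/eco-geographical matrices -> climate aggregation and
screening -> extreme-site groups -> unique-allele detection -> window
profiles -> gene neighborhood lookup -> morphometry summaries -> GPA
consensus -> Evanno ΔK (when clustering runs are provided).  Stages whose
inputs are absent are skipped with a notice; every seed and decision is
recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as dio
from . import popgen, distance, ecogeo, unique_alleles as ua
from . import morphometry as morph
from . import structure_tools
from .gpa import consensus_test as _consensus_test
from .gpa import gpa as _gpa_fit
from .gpa import panova as _panova
from .gpa import select_dimensions as _select_dimensions
from .simulate import BARLEY_CHROM_LENGTHS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run (paths may be None to skip)."""

    genotypes: str | None = None
    dialect: str = "plain_codes"
    passport: str | None = None          # accession_id, status, site_id, lat, lon, altitude_m
    climate: str | None = None
    morphometry: str | None = None
    annotation: str | None = None
    structure_runs: str | None = None
    q_matrix: str | None = None
    out_dir: str = "dartpool_out"

    filter: dio.FilterConfig = field(default_factory=dio.FilterConfig)
    season_months: tuple[int, ...] = ecogeo.DEFAULT_SEASON_MONTHS
    extreme_method: str = "tukey_tails"
    extreme_k: int = 2
    alpha: float = 0.05
    missing_policy: str = "strict"
    contrast_parameters: tuple[str, ...] | None = None   # None = all retained
    chrom_lengths: dict = field(default_factory=lambda: dict(BARLEY_CHROM_LENGTHS))
    n_perm_mantel: int = 9999
    n_perm_amova: int = 999
    n_perm_consensus: int = 499
    genotype_axes_for_gpa: int = 7
    membership_threshold: float = 0.8
    seed: int = 0


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all runnable stages; returns a dict of in-memory results.

    CSV outputs and a human-readable markdown report land in
    ``cfg.out_dir``.  A stage exception aborts the run naming the stage;
    outputs of earlier stages are retained on disk.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    results: dict = {"skipped": [], "config": dataclasses.asdict(cfg)}
    notes: list[str] = [f"seed = {cfg.seed}", f"missing_policy = {cfg.missing_policy}"]

    if cfg.genotypes is None:
        raise ValueError("a genotype matrix is required")
    passport = pd.read_csv(cfg.passport).set_index("accession_id") if cfg.passport else None

    stage = "filter"
    try:
        gm_raw = dio.read_dart_report(cfg.genotypes, cfg.dialect)
        gm, report = dio.apply_quality_filters(gm_raw, cfg.filter)
        results["filter_report"] = report
        notes.append(
            f"filtering kept {report.kept}/{report.n_input} loci "
            f"(repavg -{report.removed_repavg}, callrate -{report.removed_callrate}, "
            f"maf -{report.removed_maf}, unplaced -{report.removed_unplaced})"
        )

        stage = "diversity"
        grouping = (
            {a: passport.loc[a, "status"] for a in gm.accession_ids}
            if passport is not None and "status" in passport.columns else None
        )
        results["diversity_all"] = popgen.diversity_summary(gm)[0]
        if grouping:
            results["diversity_by_status"] = popgen.diversity_summary(gm, grouping)
        acc_ho = popgen.accession_heterozygosity(gm)
        acc_ho.to_csv(os.path.join(cfg.out_dir, "accession_heterozygosity.csv"))
        lst = popgen.locus_stats(gm)
        lst.to_csv(os.path.join(cfg.out_dir, "locus_stats.csv"))
        results["locus_stats"] = lst

        stage = "spectrum"
        spectrum = popgen.mutation_spectrum(gm.loci)
        spectrum.to_csv(os.path.join(cfg.out_dir, "mutation_spectrum.csv"))
        results["spectrum"] = spectrum

        stage = "distance"
        bm = dio.expand_codominant(gm)
        dj = distance.jaccard_distance(bm)
        dio.write_distance_matrix(dj, os.path.join(cfg.out_dir, "jaccard.csv"))
        results["jaccard"] = dj

        stage = "pcoa"
        ord_res = distance.pcoa(dj)
        ord_res.coordinates.to_csv(os.path.join(cfg.out_dir, "pcoa_coords.csv"))
        results["pcoa"] = ord_res
        notes.append(
            f"PCoA first three axes explain {ord_res.cumulative_pct(3):.2f}% "
            "(positive-eigenvalue denominator)"
        )

        stage = "amova"
        if grouping and len(set(grouping.values())) >= 2:
            results["amova_status"] = distance.amova(
                dj, grouping, n_perm=cfg.n_perm_amova, seed=cfg.seed
            )
        else:
            results["skipped"].append("amova (no status grouping)")

        stage = "windows"
        results["snp_density"] = popgen.sliding_window_profile(
            gm.loci, cfg.chrom_lengths
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- eco-geographical stages (optional inputs) -----------------------
    uset = None
    if cfg.climate is not None and passport is not None:
        stage = "ecogeo"
        try:
            climate = dio.read_monthly_climate(cfg.climate)
            table, per_year = ecogeo.aggregate_climate(climate, cfg.season_months)
            table.to_csv(os.path.join(cfg.out_dir, "ecogeo_table.csv"))
            retained, screen = ecogeo.screen_parameters(per_year, cfg.alpha)
            screen.to_csv(os.path.join(cfg.out_dir, "parameter_screen.csv"), index=False)
            results["ecogeo_retained"] = retained
            notes.append(f"climate screening retained: {retained} + altitude")

            stage = "unique-alleles"
            site_of = {
                a: passport.loc[a, "site_id"] for a in gm.accession_ids
                if a in passport.index and isinstance(passport.loc[a, "site_id"], str)
                and passport.loc[a, "site_id"]
            }
            background = [
                a for a in gm.accession_ids
                if passport.loc[a, "status"] == "landrace" and a in site_of
            ]
            contrast = cfg.contrast_parameters or tuple(retained)
            per_param_records = []
            groups_used = {}
            for param in contrast:
                if param not in retained:
                    results["skipped"].append(f"unique-alleles for {param} (screened out)")
                    continue
                try:
                    grp = ecogeo.build_extreme_groups(
                        per_year, param, method=cfg.extreme_method,
                        k=cfg.extreme_k, alpha=cfg.alpha,
                    )
                except ValueError as exc:
                    results["skipped"].append(f"unique-alleles for {param} ({exc})")
                    continue
                groups_used[param] = grp
                per_param_records.append(
                    ua.detect_unique_alleles(
                        gm, grp, background, site_of, cfg.missing_policy
                    )
                )
            uset = ua.dedupe_union(per_param_records)
            results["unique_alleles"] = uset
            results["extreme_groups"] = groups_used
            uset.to_frame().to_csv(
                os.path.join(cfg.out_dir, "unique_alleles.csv"), index=False
            )
            notes.append(
                f"unique alleles: multiplicity {uset.multiplicity_count}, "
                f"deduplicated {uset.dedup_count}"
            )
            results["unique_windows"] = ua.unique_window_profile(uset, cfg.chrom_lengths)

            stage = "mantel"
            geo_cols = {"lat", "lon"}
            if geo_cols <= set(passport.columns):
                land_geo = passport.loc[background, ["lat", "lon"]].dropna()
                if len(land_geo) >= 3:
                    sub_bm = bm.loc[land_geo.index]
                    d_gen = distance.jaccard_distance(sub_bm)
                    d_geo = distance.geographic_distance(land_geo)
                    results["mantel_geo"] = distance.mantel(
                        d_gen, d_geo, n_perm=cfg.n_perm_mantel, seed=cfg.seed
                    )
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    else:
        results["skipped"].append("ecogeo stages (no climate or passport input)")

    if cfg.annotation is not None and uset is not None and uset.records:
        stage = "genes"
        annotation = dio.read_gff3(cfg.annotation)
        clusters = ua.cluster_records(uset)
        gene_report = ua.genes_near(clusters, annotation)
        gene_report.to_csv(os.path.join(cfg.out_dir, "genes_near_clusters.csv"),
                           index=False)
        results["gene_report"] = gene_report

    per_acc = None
    if cfg.morphometry is not None:
        stage = "morphometry"
        records = dio.read_morphometry(cfg.morphometry)
        per_acc, collection = morph.summarize_morphometry(records)
        per_acc.to_csv(os.path.join(cfg.out_dir, "morphometry_accessions.csv"))
        collection.to_csv(os.path.join(cfg.out_dir, "morphometry_collection.csv"))
        results["morphometry"] = (per_acc, collection)
        if passport is not None and "status" in passport.columns:
            status = {a: passport.loc[a, "status"] for a in per_acc.index}
            results["morphometry_anova"] = morph.status_comparison(per_acc, status)
    else:
        results["skipped"].append("morphometry (no input)")

    if per_acc is not None:
        stage = "gpa"
        shared = [a for a in results["pcoa"].coordinates.index if a in per_acc.index]
        if len(shared) >= 3:
            gcoords = results["pcoa"].coordinates.loc[shared].iloc[
                :, : cfg.genotype_axes_for_gpa
            ]
            mconf = morph.morphometry_configuration(per_acc.loc[shared])
            configs = {"genotype": gcoords, "morphometry": mconf}
            fit = _gpa_fit(configs)
            results["gpa"] = fit
            results["panova"] = _panova(configs)
            rc, null, p = _consensus_test(
                configs, n_perm=cfg.n_perm_consensus, seed=cfg.seed
            )
            results["consensus_test"] = {"rc": rc, "p": p, "null": null}
            d, pct = _select_dimensions(fit, threshold=0.8)
            results["gpa_dimensions"] = (d, pct)
            fit.consensus.to_csv(os.path.join(cfg.out_dir, "gpa_consensus.csv"))
            results["panova"].to_csv(os.path.join(cfg.out_dir, "panova.csv"))
            notes.append(
                f"GPA rc = {fit.rc:.3f}, consensus p = {p:.4g}, "
                f"{d} dimensions cover >= 80%"
            )

    if cfg.structure_runs is not None:
        stage = "deltak"
        runs = structure_tools.read_structure_runs(cfg.structure_runs)
        delta = structure_tools.evanno_delta_k(runs)
        delta.to_csv(os.path.join(cfg.out_dir, "delta_k.csv"))
        results["delta_k"] = delta
        notes.append(f"Evanno best K = {structure_tools.best_k(delta)}")
        if cfg.q_matrix is not None:
            q = structure_tools.read_q_matrix(cfg.q_matrix)
            results["memberships"] = structure_tools.assign_memberships(
                q, cfg.membership_threshold
            )
    else:
        results["skipped"].append("deltak (no clustering runs)")

    _write_report(cfg, results, notes)
    return results


def _write_report(cfg: RunConfig, results: dict, notes: list[str]) -> None:
    lines = ["# dartpool run report", ""]
    lines += [f"- {n}" for n in notes]
    if results["skipped"]:
        lines += ["", "## Skipped stages", ""]
        lines += [f"- {s}" for s in results["skipped"]]
    div = results.get("diversity_all")
    if div is not None:
        lines += [
            "", "## Diversity", "",
            f"- Ho = {div.ho:.3f}, uHe = {div.uhe:.3f}, F = {div.f:.3f}",
        ]
    am = results.get("amova_status")
    if am is not None:
        lines += [
            "", "## AMOVA (biological status)", "",
            f"- among {am.pct_among:.1f}% / within {am.pct_within:.1f}%, "
            f"Phi_ST = {am.phi_st:.3f}, p = {am.p_value:.4g}",
        ]
    with open(os.path.join(cfg.out_dir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
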