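"""Synthetic landrace-collection generator with a ground-truth manifest.

Emulates the structure of a genebank collection of pooled, heterogeneous
barley landraces genotyped by reduced-representation sequencing:

* two differentiated gene pools (landraces vs breeding materials) via a
  Balding-Nichols allele-frequency model;
* each accession is a DNA pool of several seedlings — a locus segregating
  within the pool yields the "both alleles present" call, so accession-
  level heterozygosity reads as heterogeneity;
* telomere-enriched locus density along seven chromosomes and a target
  transition/transversion ratio;
* correlated monthly climate series per collection site (precipitation,
  runoff and actual evapotranspiration share a latent wetness factor;
  minimum temperature falls with altitude), with designated extreme sites
  shifted far outside the between-site spread;
* alleles planted so they are carried only by extreme-site accessions,
  clustered inside chosen genomic windows, with a toy gene annotation
  inside and outside those windows.

The :class:`TruthManifest` records everything needed to predict detector
output exactly; :func:`expected_detector_output` derives it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    CLIMATE_PARAMETERS,
    GeneAnnotation,
    GenotypeMatrix,
    MorphometryRecord,
    VALID_CHROMS,
)
from .popgen import SUBSTITUTION_TYPES, TRANSITIONS
from .unique_alleles import UniqueAlleleRecord, UniqueAlleleSet

#: approximate barley (Morex assembly) chromosome lengths in bp
BARLEY_CHROM_LENGTHS = {
    "1H": 558_535_000,
    "2H": 768_075_000,
    "3H": 699_711_000,
    "4H": 647_060_000,
    "5H": 670_030_000,
    "6H": 583_380_000,
    "7H": 657_224_000,
}


@dataclass(frozen=True)
class PlantedAlleleSpec:
    """Alleles to plant uniquely into one extreme group, inside windows."""

    parameter: str
    direction: str                                 # "low" | "high"
    windows: tuple[tuple[str, int, int], ...]      # (chrom, start_bp, end_bp)
    count: int


#: default planting: drought-index contrast with clusters on 5H and 6H
DEFAULT_PLANTED = (
    PlantedAlleleSpec(
        parameter="PDSI", direction="low",
        windows=(
            ("5H", 370_000_000, 372_000_000),
            ("5H", 552_000_000, 553_000_000),
            ("6H", 19_000_000, 20_000_000),
            ("6H", 561_000_000, 564_100_000),
        ),
        count=129,
    ),
)


@dataclass(frozen=True)
class SimulationParams:
    """Generating conditions for one synthetic collection.

    The defaults mirror the study system this pipeline targets: 63
    accessions (48 landrace pools of 8 seedlings plus 15 breeding
    materials), ~9.7k placed SNP loci with telomere-enriched density and a
    transition/transversion ratio of 1.48, 47 collection sites with
    1958-2020 monthly climate, and 129 drought-contrast alleles planted in
    clusters on 5H and 6H.
    """

    n_landraces: int = 48
    n_breeding: int = 15
    pool_size: int = 8
    n_loci: int = 9737
    chrom_lengths: dict = field(default_factory=lambda: dict(BARLEY_CHROM_LENGTHS))
    telomere_weight: float = 0.7
    target_ts_tv: float = 1.48
    fst_like: float = 0.13
    heterogeneity_landrace: float = 0.34
    heterogeneity_breeding: float = 0.04
    missing_rate: float = 0.01
    low_quality_fraction: float = 0.05
    n_sites: int = 47
    n_extreme_sites: int = 2
    year_range: tuple[int, int] = (1958, 2020)
    site_invariant_params: tuple[str, ...] = ("tmax", "def", "srad", "pet")
    planted: tuple[PlantedAlleleSpec, ...] = DEFAULT_PLANTED
    grains_per_accession: int = 100
    morph_effect_sd: float = 3.0     # status shift on area/perimeter/length

    def __post_init__(self) -> None:
        for name in ("n_landraces", "n_breeding", "pool_size", "n_loci", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("telomere_weight", "fst_like", "heterogeneity_landrace",
                     "heterogeneity_breeding", "missing_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for spec in self.planted:
            for chrom, start, end in spec.windows:
                if end > self.chrom_lengths[chrom]:
                    raise ValueError(
                        f"planted window {chrom}:{start}-{end} exceeds chromosome length"
                    )


@dataclass
class TruthManifest:
    """Ground truth of one simulated collection."""

    gene_pool: dict            # accession -> "landrace" | "breeding"
    site_of_accession: dict    # landrace accession -> site id
    heterogeneity: dict        # accession -> h used
    extreme_sites: dict        # parameter -> {"low": [...], "high": [...]}
    planted_records: list      # dicts mirroring UniqueAlleleRecord fields
    params: dict               # generating parameter values

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class SyntheticCollection:
    genotypes: GenotypeMatrix
    sites: pd.DataFrame                  # site_id-indexed lat, lon, altitude_m
    site_of_accession: dict
    status: dict                         # accession -> biological status
    climate: pd.DataFrame                # long monthly table
    morphometry: list
    annotation: list
    manifest: TruthManifest


def simulate_collection(
    params: SimulationParams | None = None, seed: int = 0
) -> SyntheticCollection:
    """Generate a complete synthetic collection, reproducible from *seed*."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)

    accessions, status, site_of = _make_accessions(params, rng)
    sites = _make_sites(params, rng)
    extreme_sites = _designate_extremes(params, rng, list(sites.index))
    climate = _make_climate(params, rng, sites, extreme_sites)
    loci = _make_loci(params, rng)
    calls = _make_calls(params, rng, accessions, status, loci)
    planted = _plant_alleles(params, rng, calls, loci, site_of, extreme_sites, status)
    _apply_missing_and_quality(params, rng, calls, loci, planted)
    _break_accidental_exclusives(rng, calls, site_of, extreme_sites, planted, status)
    loci["call_rate"] = calls.notna().mean(axis=0).values
    gm = GenotypeMatrix(calls, loci)
    morph = _make_morphometry(params, rng, accessions, status)
    annotation = _make_annotation(params, rng)
    manifest = TruthManifest(
        gene_pool={a: status[a] for a in accessions},
        site_of_accession=dict(site_of),
        heterogeneity={
            a: (params.heterogeneity_landrace if status[a] == "landrace"
                else params.heterogeneity_breeding)
            for a in accessions
        },
        extreme_sites={p: {k: list(v) for k, v in d.items()}
                       for p, d in extreme_sites.items()},
        planted_records=planted,
        params={
            "n_landraces": params.n_landraces, "n_breeding": params.n_breeding,
            "pool_size": params.pool_size, "n_loci": params.n_loci,
            "fst_like": params.fst_like, "target_ts_tv": params.target_ts_tv,
            "seed": seed,
        },
    )
    return SyntheticCollection(
        genotypes=gm, sites=sites, site_of_accession=site_of, status=status,
        climate=climate, morphometry=morph, annotation=annotation, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _make_accessions(params, rng):
    accessions = [f"ACC{i + 1:03d}" for i in range(params.n_landraces + params.n_breeding)]
    status = {}
    site_of = {}
    for i, acc in enumerate(accessions):
        if i < params.n_landraces:
            status[acc] = "landrace"
            site_of[acc] = f"S{(i % params.n_sites) + 1:02d}"
        else:
            status[acc] = "breeding"
    return accessions, status, site_of


def _make_sites(params, rng) -> pd.DataFrame:
    ids = [f"S{i + 1:02d}" for i in range(params.n_sites)]
    lat = rng.uniform(29.0, 35.5, params.n_sites)
    lon = rng.uniform(-9.5, -2.0, params.n_sites)
    altitude = rng.uniform(100.0, 1800.0, params.n_sites)
    return pd.DataFrame(
        {"lat": lat, "lon": lon, "altitude_m": altitude},
        index=pd.Index(ids, name="site_id"),
    )


def _designate_extremes(params, rng, site_ids) -> dict:
    out = {}
    for spec in params.planted:
        if spec.parameter in out:
            continue
        chosen = [str(s) for s in
                  rng.choice(site_ids, size=2 * params.n_extreme_sites, replace=False)]
        out[spec.parameter] = {
            "low": chosen[: params.n_extreme_sites],
            "high": chosen[params.n_extreme_sites:],
        }
    return out


#: site-mean base level and spread, monthly noise sd, per parameter
_CLIMATE_MODEL = {
    # parameter: (base, site_sd, month_sd)
    "tmax": (23.0, 0.0, 1.2),      # site-invariant by default
    "tmin": (9.0, 2.0, 1.0),
    "aet": (30.0, 10.0, 3.0),
    "def": (95.0, 0.0, 8.0),       # site-invariant by default
    "pet": (125.0, 0.0, 9.0),      # site-invariant by default
    "ppt": (40.0, 18.0, 6.0),
    "PDSI": (-0.7, 0.12, 0.25),
    "srad": (215.0, 0.0, 10.0),    # site-invariant by default
    "q": (12.0, 6.0, 1.5),
    "soil": (45.0, 20.0, 5.0),
    "ws": (3.5, 0.45, 0.3),
}


def _make_climate(params, rng, sites, extreme_sites) -> pd.DataFrame:
    """Monthly long table with a shared latent wetness factor per site.

    ppt, q, aet and soil all load on the wetness factor (giving the > 0.9
    between-site correlations); tmin is tied negatively to altitude.
    Designated extreme sites get their parameter mean shifted by +-6
    monthly noise sd, far beyond the between-site spread.
    """
    years = np.arange(params.year_range[0], params.year_range[1] + 1)
    months = np.arange(1, 13)
    n_sites = len(sites)
    wet = rng.normal(0.0, 1.0, n_sites)                    # latent wetness
    alt_z = (
        (sites["altitude_m"] - sites["altitude_m"].mean())
        / sites["altitude_m"].std(ddof=0)
    ).to_numpy()

    site_means = {}
    for p, (base, site_sd, month_sd) in _CLIMATE_MODEL.items():
        if p in params.site_invariant_params:
            mu = np.full(n_sites, base)
        elif p in ("ppt", "q", "aet", "soil"):
            mu = base + site_sd * (0.97 * wet + 0.243 * rng.normal(size=n_sites))
        elif p == "tmin":
            mu = base + site_sd * (-0.9 * alt_z + 0.436 * rng.normal(size=n_sites))
        else:
            mu = base + site_sd * rng.normal(size=n_sites)
        site_means[p] = mu

    for param, tails in extreme_sites.items():
        _, _, month_sd = _CLIMATE_MODEL[param]
        idx = {s: i for i, s in enumerate(sites.index)}
        for s in tails["low"]:
            site_means[param][idx[s]] -= 6.0 * month_sd
        for s in tails["high"]:
            site_means[param][idx[s]] += 6.0 * month_sd

    season = 1.0 + 0.25 * np.sin(2 * np.pi * (months - 3) / 12.0)
    frames = []
    for p in CLIMATE_PARAMETERS:
        base, site_sd, month_sd = _CLIMATE_MODEL[p]
        mu = site_means[p]
        vals = (
            mu[:, None, None] * (season[None, None, :] if p != "PDSI" else 1.0)
            + rng.normal(0.0, month_sd, (n_sites, len(years), 12))
        )
        df = pd.DataFrame(
            {
                "site_id": np.repeat(sites.index.to_numpy(), len(years) * 12),
                "parameter": p,
                "year": np.tile(np.repeat(years, 12), n_sites),
                "month": np.tile(months, n_sites * len(years)),
                "value": vals.reshape(-1),
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _telomere_positions(rng, n, length, weight):
    """Positions from a telomere-peaked mixture on [1, length]."""
    u = np.empty(n)
    tel = rng.random(n) < weight
    b = rng.beta(0.5, 2.5, n)                 # mass near 0
    side = rng.random(n) < 0.5
    u[tel] = np.where(side[tel], b[tel], 1.0 - b[tel])
    u[~tel] = rng.random((~tel).sum())
    return np.maximum(1, (u * length).astype(np.int64))


def _make_loci(params, rng) -> pd.DataFrame:
    lengths = params.chrom_lengths
    total = sum(lengths.values())
    counts = {c: int(round(params.n_loci * l / total)) for c, l in lengths.items()}
    drift = params.n_loci - sum(counts.values())
    counts[list(lengths)[0]] += drift
    rows = []
    ts_types = [t for t in SUBSTITUTION_TYPES if t in TRANSITIONS]
    tv_types = [t for t in SUBSTITUTION_TYPES if t not in TRANSITIONS]
    p_ts = params.target_ts_tv / (1.0 + params.target_ts_tv)
    i = 0
    for chrom in VALID_CHROMS:
        n = counts[chrom]
        pos = np.sort(_telomere_positions(rng, n, lengths[chrom], params.telomere_weight))
        for p_bp in pos:
            i += 1
            if rng.random() < p_ts:
                t = ts_types[rng.integers(len(ts_types))]
            else:
                t = tv_types[rng.integers(len(tv_types))]
            ref, alt = t.split(">")
            rows.append(
                {
                    "locus_id": f"SNP{i:06d}", "chrom": chrom, "pos_bp": int(p_bp),
                    "ref_allele": ref, "alt_allele": alt,
                    "rep_avg": 1.0, "call_rate": 1.0,
                }
            )
    return pd.DataFrame(rows).set_index("locus_id")


def _make_calls(params, rng, accessions, status, loci) -> pd.DataFrame:
    n_loci = len(loci)
    # ascertained marker panels are enriched for intermediate frequencies;
    # a symmetric Beta keeps most loci informative
    p0 = np.clip(rng.beta(4.0, 4.0, n_loci), 0.02, 0.98)
    f = params.fst_like
    pool_freq = {}
    for pool in ("landrace", "breeding"):
        if f <= 0:
            pool_freq[pool] = p0
        else:
            a, b = p0 * (1 - f) / f, (1 - p0) * (1 - f) / f
            pool_freq[pool] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    gametes = 2 * params.pool_size
    rows = []
    for acc in accessions:
        p = pool_freq[status[acc]]
        h = (params.heterogeneity_landrace if status[acc] == "landrace"
             else params.heterogeneity_breeding)
        seg = rng.random(n_loci) < h
        k = rng.binomial(gametes, p)
        code_seg = np.where(k == 0, 0.0, np.where(k == gametes, 2.0, 1.0))
        code_fix = np.where(rng.random(n_loci) < p, 2.0, 0.0)
        rows.append(np.where(seg, code_seg, code_fix))
    return pd.DataFrame(np.array(rows), index=pd.Index(accessions, name="accession_id"),
                        columns=loci.index)


def _plant_alleles(params, rng, calls, loci, site_of, extreme_sites, status) -> list:
    """Overwrite selected loci so the alt allele is exclusive to a group."""
    planted = []
    used = set()
    landraces = [a for a in calls.index if status[a] == "landrace"]
    for spec in params.planted:
        tails = extreme_sites[spec.parameter]
        group_sites = set(tails[spec.direction])
        members = [a for a in landraces if site_of.get(a) in group_sites]
        if not members:
            raise ValueError(f"no accession maps to extreme sites for {spec.parameter}")
        candidates = [lid for lid in loci.index if lid not in used]
        chosen = rng.choice(candidates, size=spec.count, replace=False)
        for j, lid in enumerate(chosen):
            used.add(lid)
            chrom, start, end = spec.windows[int(rng.integers(len(spec.windows)))]
            loci.loc[lid, ["chrom", "pos_bp"]] = [chrom, int(rng.integers(start, end + 1))]
            loci.loc[lid, "rep_avg"] = 1.0
            calls[lid] = 0.0                                 # background: hom ref
            n_carriers = int(rng.integers(1, len(members) + 1))
            carriers = list(rng.choice(members, size=n_carriers, replace=False))
            # pools carry both alleles; a lone carrier is fixed for the
            # alternative so the planted allele dose stays above the
            # collection-level MAF filter (> 0.01 of 2N)
            calls.loc[carriers, lid] = 1.0 if n_carriers > 1 else 2.0
            planted.append(
                {
                    "locus_id": lid, "allele": "alt", "parameter": spec.parameter,
                    "direction": spec.direction, "carriers": sorted(carriers),
                    "chrom": chrom, "pos_bp": int(loci.loc[lid, "pos_bp"]),
                }
            )
    return planted


def _apply_missing_and_quality(params, rng, calls, loci, planted) -> None:
    planted_ids = {p["locus_id"] for p in planted}
    if params.missing_rate > 0:
        mask = rng.random(calls.shape) < params.missing_rate
        for j, lid in enumerate(calls.columns):
            if lid in planted_ids:
                mask[:, j] = False
        calls.values[mask] = np.nan
    low = rng.random(len(loci)) < params.low_quality_fraction
    rep = np.clip(1.0 - np.abs(rng.normal(0.0, 0.015, len(loci))), 0.0, 1.0)
    rep[low] = rng.uniform(0.80, 0.949, low.sum())
    keep_perfect = loci.index.isin(planted_ids)
    rep[keep_perfect] = 1.0
    loci["rep_avg"] = rep


def _break_accidental_exclusives(rng, calls, site_of, extreme_sites, planted, status) -> None:
    """Guarantee that planted alleles are the only group-exclusive ones.

    For every non-planted locus and extreme group, if an allele happens to
    be carried only inside the group, one outside landrace is set to the
    both-alleles call, destroying the accidental exclusivity without
    touching the planted records.
    """
    planted_ids = {p["locus_id"] for p in planted}
    landraces = [a for a in calls.index if status[a] == "landrace"]
    for parameter, tails in extreme_sites.items():
        for direction in ("low", "high"):
            members = [a for a in landraces if site_of.get(a) in set(tails[direction])]
            outside = [a for a in landraces if a not in set(members)]
            if not members or not outside:
                continue
            sub_in = calls.loc[members]
            sub_out = calls.loc[outside]
            for allele, codes in (("ref", (0.0, 1.0)), ("alt", (1.0, 2.0))):
                carried_in = sub_in.isin(codes).any(axis=0)
                carried_out = sub_out.isin(codes).any(axis=0)
                exclusive = carried_in & ~carried_out
                for lid in calls.columns[exclusive]:
                    if lid in planted_ids:
                        continue
                    fix = outside[int(rng.integers(len(outside)))]
                    calls.loc[fix, lid] = 1.0


_MORPH_BASE = {
    "area": (24.9, 1.6, 1.0), "perimeter": (31.6, 1.6, 0.9),
    "length": (10.15, 0.6, 0.35), "width": (3.10, 0.10, 0.08),
    "color_r": (164.5, 5.0, 4.0), "color_g": (138.8, 4.5, 4.0),
    "color_b": (112.5, 4.0, 4.0),
}


def _make_morphometry(params, rng, accessions, status) -> list:
    """Grain tables with a status effect on area, perimeter and length."""
    records = []
    for acc in accessions:
        shift = params.morph_effect_sd if status[acc] == "breeding" else 0.0
        acc_mean = {}
        for p, (base, acc_sd, grain_sd) in _MORPH_BASE.items():
            eff = shift * acc_sd if p in ("area", "perimeter", "length") else 0.0
            acc_mean[p] = base + eff + rng.normal(0.0, acc_sd)
        for g in range(params.grains_per_accession):
            vals = {
                p: max(0.05, acc_mean[p] + rng.normal(0.0, _MORPH_BASE[p][2]))
                for p in _MORPH_BASE
            }
            for c in ("color_r", "color_g", "color_b"):
                vals[c] = float(np.clip(vals[c], 0.0, 255.0))
            records.append(
                MorphometryRecord(accession_id=acc, grain_index=g + 1, **vals)
            )
    return records


def _make_annotation(params, rng) -> list:
    """Toy genes inside every planted window plus decoys elsewhere.

    All genes are synthetic stand-ins, named ``GENE_<chrom>_<n>``.
    """
    genes = []
    i = 0
    for spec in params.planted:
        for chrom, start, end in spec.windows:
            i += 1
            mid = (start + end) // 2
            half = max(1000, (end - start) // 10)
            genes.append(
                GeneAnnotation(
                    gene_id=f"GENE_{chrom}_{i:03d}", chrom=chrom,
                    start_bp=max(1, mid - half), end_bp=mid + half,
                    description="synthetic drought-window gene",
                )
            )
    for chrom, length in params.chrom_lengths.items():
        for _ in range(2):
            i += 1
            start = int(rng.integers(1, length - 10_000))
            genes.append(
                GeneAnnotation(
                    gene_id=f"GENE_{chrom}_{i:03d}", chrom=chrom,
                    start_bp=start, end_bp=start + int(rng.integers(2_000, 10_000)),
                    description="synthetic background gene",
                )
            )
    return sorted(genes, key=lambda g: (g.chrom, g.start_bp))


def expected_detector_output(manifest: TruthManifest) -> UniqueAlleleSet:
    """The exact record set strict-policy detection must return on
    complete (no-missing) synthetic data."""
    records = [
        UniqueAlleleRecord(
            locus_id=p["locus_id"], allele=p["allele"], parameter=p["parameter"],
            direction=p["direction"], carriers=tuple(p["carriers"]),
            chrom=p["chrom"], pos_bp=p["pos_bp"],
        )
        for p in manifest.planted_records
    ]
    return UniqueAlleleSet(records=records)


def write_collection(coll: SyntheticCollection, outdir) -> dict:
    """Write every input format the pipeline readers accept.

    Produces the genotype report (plain_codes dialect), passport table
    (status, site, coordinates, altitude), long monthly climate table,
    per-grain morphometry, GFF3 annotation and the truth manifest JSON.
    Returns the path map.
    """
    import os

    from .io import morphometry_frame, write_dart_report, write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.csv"),
        "passport": os.path.join(outdir, "passport.csv"),
        "climate": os.path.join(outdir, "climate.csv"),
        "morphometry": os.path.join(outdir, "morphometry.csv"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_dart_report(coll.genotypes, paths["genotypes"])
    passport = pd.DataFrame(
        {
            "accession_id": coll.genotypes.accession_ids,
            "status": [coll.status[a] for a in coll.genotypes.accession_ids],
            "site_id": [coll.site_of_accession.get(a, "") for a in
                        coll.genotypes.accession_ids],
        }
    )
    passport = passport.merge(
        coll.sites.reset_index(), on="site_id", how="left"
    )
    passport.to_csv(paths["passport"], index=False)
    coll.climate.to_csv(paths["climate"], index=False)
    morphometry_frame(coll.morphometry).to_csv(paths["morphometry"], index=False)
    write_gff3(coll.annotation, paths["annotation"])
    coll.manifest.to_json(paths["manifest"])
    return paths


def simulate_structure_runs(
    true_k: int = 2, k_range: tuple[int, int] = (1, 15), n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic clustering run summaries with a likelihood elbow at *true_k*."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_range[0], k_range[1] + 1):
        mean = -5000.0 + 800.0 * min(k, true_k) + 15.0 * max(0, k - true_k)
        for rep in range(1, n_replicates + 1):
            rows.append({"K": k, "replicate": rep,
                         "ln_prob": mean + rng.normal(0.0, 5.0)})
    return pd.DataFrame(rows)
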