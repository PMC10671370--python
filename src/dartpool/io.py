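"""Readers, writers and quality filtering for the pipeline's external formats.

The central in-memory object is :class:`GenotypeMatrix`: accessions x loci
codominant calls from pooled-DNA DArTseq genotyping.  Because each accession
is a DNA pool of several seedlings, the heterozygous code means "both alleles
present somewhere in the pool", not heterozygosity of an individual plant.

Call codes
----------
0  homozygous reference (only the reference allele seen in the pool)
1  both alleles present in the pool
2  homozygous alternative
NaN  missing call (accepted on disk as "-", "NA" or an empty cell)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CHROMS = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")
UNKNOWN_CHROM = "unknown"
NUCLEOTIDES = ("A", "C", "G", "T")

#: columns expected in the locus metadata table, in canonical order
LOCUS_COLUMNS = ("chrom", "pos_bp", "ref_allele", "alt_allele", "rep_avg", "call_rate")

#: the accepted climate parameter vocabulary
CLIMATE_PARAMETERS = (
    "tmax", "tmin", "aet", "def", "pet", "ppt", "PDSI", "srad", "q", "soil", "ws",
)

MISSING_TOKENS = {"-", "NA", "", "nan", "NaN"}


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPLocus:
    """Metadata for one biallelic SNP marker."""

    locus_id: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    rep_avg: float
    call_rate: float

    def __post_init__(self) -> None:
        if self.chrom not in VALID_CHROMS and self.chrom != UNKNOWN_CHROM:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.locus_id}: ref and alt alleles are equal")
        if self.chrom != UNKNOWN_CHROM and self.pos_bp < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1 (1-based)")
        for frac, name in ((self.rep_avg, "rep_avg"), (self.call_rate, "call_rate")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.locus_id}: {name}={frac} outside [0, 1]")


class GenotypeMatrix:
    """Accessions x loci codominant call matrix with locus metadata.

    Parameters
    ----------
    calls
        DataFrame indexed by accession id, one column per locus id, values
        in {0, 1, 2, NaN}.
    loci
        DataFrame indexed by locus id with columns ``chrom``, ``pos_bp``,
        ``ref_allele``, ``alt_allele``, ``rep_avg``, ``call_rate``, in the
        same order as the columns of *calls*.
    """

    def __init__(self, calls: pd.DataFrame, loci: pd.DataFrame):
        calls = calls.astype(float)
        if not calls.index.is_unique:
            raise ValueError("accession ids are not unique")
        if not calls.columns.is_unique:
            raise ValueError("locus ids are not unique")
        if list(calls.columns) != list(loci.index):
            raise ValueError("calls columns and loci index disagree")
        missing_cols = [c for c in LOCUS_COLUMNS if c not in loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns: {missing_cols}")
        bad = ~(calls.isin([0.0, 1.0, 2.0]) | calls.isna())
        if bad.any().any():
            acc = calls.index[bad.any(axis=1)][0]
            raise ValueError(f"invalid call code in accession {acc!r}")
        calls = calls.rename_axis(index="accession_id", columns="locus_id")
        self.calls = calls
        self.loci = loci[list(LOCUS_COLUMNS)].copy().rename_axis(index="locus_id")

    # -- basic introspection ------------------------------------------------
    @property
    def accession_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        locus_ids = list(locus_ids)
        return GenotypeMatrix(self.calls[locus_ids], self.loci.loc[locus_ids])

    def subset_accessions(self, accession_ids) -> "GenotypeMatrix":
        accession_ids = list(accession_ids)
        return GenotypeMatrix(self.calls.loc[accession_ids], self.loci)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.calls, other.calls, check_dtype=False)
            pd.testing.assert_frame_equal(
                self.loci, other.loci, check_dtype=False, check_exact=False
            )
        except AssertionError:
            return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_accessions} accessions x {self.n_loci} loci)"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for marker quality filtering.

    Defaults follow common DArTseq practice for germplasm characterization:
    reproducibility and call rate at least 0.95, minor allele frequency
    strictly above 0.01, and unplaced markers dropped.
    """

    min_rep_avg: float = 0.95
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    require_known_chrom: bool = True

    def __post_init__(self) -> None:
        for v, name in (
            (self.min_rep_avg, "min_rep_avg"),
            (self.min_call_rate, "min_call_rate"),
            (self.min_maf, "min_maf"),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class FilterReport:
    """Per-criterion removal counts, evaluated in fixed order."""

    n_input: int
    removed_repavg: int
    removed_callrate: int
    removed_maf: int
    removed_unplaced: int
    kept: int

    def __post_init__(self) -> None:
        total = (
            self.removed_repavg + self.removed_callrate + self.removed_maf
            + self.removed_unplaced + self.kept
        )
        if total != self.n_input:
            raise ValueError("filter report counts do not sum to input loci")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene feature from a GFF3 annotation (1-based inclusive coords)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


@dataclass(frozen=True)
class MorphometryRecord:
    """One grain's measurements from flatbed-scanner image analysis."""

    accession_id: str
    grain_index: int
    area: float       # mm^2
    perimeter: float  # mm
    length: float     # mm
    width: float      # mm
    color_r: float    # 8-bit channel mean
    color_g: float
    color_b: float

    def __post_init__(self) -> None:
        for v, name in (
            (self.area, "area"), (self.perimeter, "perimeter"),
            (self.length, "length"), (self.width, "width"),
        ):
            if not v > 0:
                raise ValueError(f"{self.accession_id}: {name}={v} must be > 0")
        for v, name in (
            (self.color_r, "color_r"), (self.color_g, "color_g"),
            (self.color_b, "color_b"),
        ):
            if not 0 <= v <= 255:
                raise ValueError(f"{self.accession_id}: {name}={v} outside [0, 255]")


# ---------------------------------------------------------------------------
# DArT report reading / writing
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ("LocusID", "Chrom", "Pos", "Ref", "Alt", "RepAvg", "CallRate")


def _parse_code(token) -> float:
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return np.nan
    try:
        v = float(s)
    except ValueError:
        raise FormatError(f"unparseable call {token!r}") from None
    if v not in (0.0, 1.0, 2.0):
        raise FormatError(f"call code {token!r} not in {{0, 1, 2}}")
    return v


def read_dart_report(path, dialect: str = "plain_codes") -> GenotypeMatrix:
    """Read a DArTseq-style SNP report into a :class:`GenotypeMatrix`.

    Three CSV dialects are supported:

    ``plain_codes``
        one row per locus, cells already coded 0/1/2/missing with our
        convention (1 = both alleles present in the pool);
    ``one_row_snp``
        one row per locus, DArT single-row scoring where 0 = reference
        homozygote, 1 = alternative homozygote, 2 = heterozygous/both;
    ``two_row``
        two rows per locus (reference-allele presence row then
        alternative-allele presence row), collapsed into codes.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"report header lacks required column(s): {missing}")
    acc_cols = [c for c in df.columns if c not in _METADATA_COLUMNS]
    if not acc_cols:
        raise FormatError("report declares no accession columns")

    if dialect == "two_row":
        return _collapse_two_row(df, acc_cols)
    if dialect not in ("plain_codes", "one_row_snp"):
        raise ValueError(f"unknown dialect {dialect!r}")

    codes = df[acc_cols].map(_parse_code)
    if dialect == "one_row_snp":
        remap = {0.0: 0.0, 1.0: 2.0, 2.0: 1.0}
        codes = codes.map(lambda v: remap.get(v, v))
    calls = codes.T
    calls.columns = df["LocusID"].tolist()
    calls.index.name = "accession_id"
    loci = _loci_frame(df)
    return GenotypeMatrix(calls, loci)


def _loci_frame(df: pd.DataFrame) -> pd.DataFrame:
    loci = pd.DataFrame(
        {
            "chrom": df["Chrom"].astype(str).values,
            "pos_bp": df["Pos"].astype(int).values,
            "ref_allele": df["Ref"].astype(str).values,
            "alt_allele": df["Alt"].astype(str).values,
            "rep_avg": df["RepAvg"].astype(float).values,
            "call_rate": df["CallRate"].astype(float).values,
        },
        index=pd.Index(df["LocusID"].tolist(), name="locus_id"),
    )
    if not loci.index.is_unique:
        raise FormatError("duplicated locus ids in report")
    return loci


def _collapse_two_row(df: pd.DataFrame, acc_cols: list[str]) -> GenotypeMatrix:
    if len(df) % 2 != 0:
        raise FormatError("two_row report has an odd number of rows")
    code_table = {(1.0, 0.0): 0.0, (1.0, 1.0): 1.0, (0.0, 1.0): 2.0}
    records, call_rows = [], []
    for i in range(0, len(df), 2):
        top, bot = df.iloc[i], df.iloc[i + 1]
        if top["LocusID"] != bot["LocusID"]:
            raise FormatError(
                f"inconsistent row pairing near line {i + 2}: "
                f"{top['LocusID']!r} vs {bot['LocusID']!r}"
            )
        records.append(top)
        row = []
        for c in acc_cols:
            ref_p, alt_p = _parse_presence(top[c]), _parse_presence(bot[c])
            if np.isnan(ref_p) or np.isnan(alt_p) or (ref_p, alt_p) == (0.0, 0.0):
                row.append(np.nan)
            else:
                row.append(code_table[(ref_p, alt_p)])
        call_rows.append(row)
    meta = pd.DataFrame(records)
    calls = pd.DataFrame(call_rows, columns=acc_cols, index=meta["LocusID"].tolist()).T
    calls.index.name = "accession_id"
    return GenotypeMatrix(calls, _loci_frame(meta))


def _parse_presence(token) -> float:
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return np.nan
    if s not in ("0", "1", "0.0", "1.0"):
        raise FormatError(f"presence cell {token!r} not 0/1/missing")
    return float(float(s))


def write_dart_report(gm: GenotypeMatrix, path) -> None:
    """Write a ``plain_codes`` dialect report; missing calls become '-'."""
    meta = pd.DataFrame(
        {
            "LocusID": gm.locus_ids,
            "Chrom": gm.loci["chrom"].values,
            "Pos": gm.loci["pos_bp"].values,
            "Ref": gm.loci["ref_allele"].values,
            "Alt": gm.loci["alt_allele"].values,
            "RepAvg": gm.loci["rep_avg"].values,
            "CallRate": gm.loci["call_rate"].values,
        }
    )
    codes = gm.calls.T.reset_index(drop=True)
    codes = codes.map(lambda v: "-" if pd.isna(v) else str(int(v)))
    pd.concat([meta, codes], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def allele_frequency_alt(gm: GenotypeMatrix) -> pd.Series:
    """Per-locus alternative-allele frequency.

    Each pooled accession is weighted as one diploid equivalent:
    ``p_alt = (n_het + 2 n_hom_alt) / (2 n_non_missing)``.  All-missing
    loci yield NaN.
    """
    calls = gm.calls
    n_non_missing = calls.notna().sum(axis=0)
    alt_doses = (calls == 1.0).sum(axis=0) + 2 * (calls == 2.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt_doses / (2.0 * n_non_missing)
    p_alt[n_non_missing == 0] = np.nan
    p_alt.name = "p_alt"
    return p_alt


def apply_quality_filters(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci failing reproducibility, call rate, MAF or placement.

    The criteria are evaluated in the fixed order RepAvg -> CallRate ->
    MAF -> chromosome placement so that the per-criterion removal counts
    in the report are reproducible.  MAF uses a strict ``>`` comparison.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    cfg = cfg or FilterConfig()

    remaining = gm.loci.index
    fail_rep = remaining[gm.loci.loc[remaining, "rep_avg"] < cfg.min_rep_avg]
    remaining = remaining.difference(fail_rep, sort=False)

    fail_cr = remaining[gm.loci.loc[remaining, "call_rate"] < cfg.min_call_rate]
    remaining = remaining.difference(fail_cr, sort=False)

    p_alt = allele_frequency_alt(gm)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf_ok = maf.loc[remaining] > cfg.min_maf
    fail_maf = remaining[~maf_ok.fillna(False)]
    remaining = remaining.difference(fail_maf, sort=False)

    if cfg.require_known_chrom:
        placed = gm.loci.loc[remaining, "chrom"] != UNKNOWN_CHROM
        fail_place = remaining[~placed]
        remaining = remaining.difference(fail_place, sort=False)
    else:
        fail_place = remaining[:0]

    keep = [lid for lid in gm.locus_ids if lid in set(remaining)]
    report = FilterReport(
        n_input=gm.n_loci,
        removed_repavg=len(fail_rep),
        removed_callrate=len(fail_cr),
        removed_maf=len(fail_maf),
        removed_unplaced=len(fail_place),
        kept=len(keep),
    )
    if not keep:
        raise ValueError("empty after filtering: no locus passed all criteria")
    return gm.subset_loci(keep), report


# ---------------------------------------------------------------------------
# codominant binary expansion
# ---------------------------------------------------------------------------

def expand_codominant(gm: GenotypeMatrix) -> pd.DataFrame:
    """Expand calls into two presence/absence columns per locus.

    Column order is ``locus:ref, locus:alt`` per locus, preserving locus
    order.  Codes map as 0 -> (1,0), 1 -> (1,1), 2 -> (0,1); missing
    propagates to both columns.
    """
    calls = gm.calls
    ref_present = calls.isin([0.0, 1.0]).astype(float).where(calls.notna())
    alt_present = calls.isin([1.0, 2.0]).astype(float).where(calls.notna())
    cols = {}
    for lid in gm.locus_ids:
        cols[f"{lid}:ref"] = ref_present[lid]
        cols[f"{lid}:alt"] = alt_present[lid]
    return pd.DataFrame(cols, index=calls.index)


def collapse_binary(bm: pd.DataFrame, loci: pd.DataFrame) -> GenotypeMatrix:
    """Inverse of :func:`expand_codominant` (exact on complete data)."""
    locus_ids = list(loci.index)
    data = {}
    for lid in locus_ids:
        ref, alt = bm[f"{lid}:ref"], bm[f"{lid}:alt"]
        code = pd.Series(np.nan, index=bm.index)
        code[(ref == 1.0) & (alt == 0.0)] = 0.0
        code[(ref == 1.0) & (alt == 1.0)] = 1.0
        code[(ref == 0.0) & (alt == 1.0)] = 2.0
        data[lid] = code
    return GenotypeMatrix(pd.DataFrame(data, index=bm.index), loci)


# ---------------------------------------------------------------------------
# GFF3 / climate / morphometry / distance matrix I/O
# ---------------------------------------------------------------------------

def read_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneAnnotation]:
    """Parse gene features from a GFF3 file (1-based inclusive coordinates).

    Features without an ``ID`` attribute are skipped with a logged warning.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                continue
            seqid, _, ftype, start, end, _, _, _, attrs = parts
            if ftype not in feature_types:
                continue
            attr_map = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            if "ID" not in attr_map:
                logger.warning("gene feature without ID attribute skipped: %s", line)
                continue
            genes.append(
                GeneAnnotation(
                    gene_id=attr_map["ID"],
                    chrom=seqid,
                    start_bp=int(start),
                    end_bp=int(end),
                    description=attr_map.get("description", attr_map.get("Note", "")),
                )
            )
    return genes


def write_gff3(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\tdartpool\tgene\t{g.start_bp}\t{g.end_bp}\t.\t+\t.\t{attrs}\n"
            )


def read_monthly_climate(path) -> pd.DataFrame:
    """Read a long-format monthly climate table.

    Expected columns: ``site_id, parameter, year, month, value`` (optionally
    ``lat, lon, altitude_m``).  Parameter names must come from the
    11-name vocabulary.
    """
    df = pd.read_csv(path)
    required = {"site_id", "parameter", "year", "month", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"climate table lacks columns: {sorted(missing)}")
    unknown = set(df["parameter"]) - set(CLIMATE_PARAMETERS)
    if unknown:
        raise FormatError(
            f"unknown climate parameter(s) {sorted(unknown)}; "
            f"accepted vocabulary: {list(CLIMATE_PARAMETERS)}"
        )
    if not df["month"].between(1, 12).all():
        raise FormatError("month values must lie in 1..12")
    return df


def read_morphometry(path) -> list[MorphometryRecord]:
    """Read a per-grain morphometry CSV (GrainScan-style columns)."""
    df = pd.read_csv(path)
    required = [
        "accession_id", "grain_index", "area", "perimeter", "length", "width",
        "color_r", "color_g", "color_b",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"morphometry table lacks columns: {missing}")
    return [
        MorphometryRecord(
            accession_id=str(r.accession_id), grain_index=int(r.grain_index),
            area=float(r.area), perimeter=float(r.perimeter),
            length=float(r.length), width=float(r.width),
            color_r=float(r.color_r), color_g=float(r.color_g),
            color_b=float(r.color_b),
        )
        for r in df.itertuples()
    ]


def morphometry_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_distance_matrix(dm, path) -> None:
    """Write a labeled square distance matrix as CSV (bit-exact round trip)."""
    df = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
    df.to_csv(path)  # pandas writes shortest round-trip float repr


def read_distance_matrix(path, metric: str = "unknown"):
    from .distance import DistanceMatrix

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row and column labels differ")
    return DistanceMatrix(labels=list(df.index), values=df.values, metric=metric)
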