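"""dartpool: diversity analysis of pooled-sample SNP genotyping in
heterogeneous landrace collections.

The pipeline covers marker quality filtering, pooled-sample diversity
coefficients (Ho as accession heterogeneity, uHe, F), the substitution
spectrum, Jaccard/Gower distances with PCoA/PCA, AMOVA and Mantel tests,
eco-geographical site screening, detection of alleles unique to
extreme-environment accessions with genomic-window localization and gene
lookup, grain-morphometry summaries, Bayesian-clustering post-processing
(Evanno ΔK, membership thresholds), and a Generalized Procrustes consensus
of genotype and phenotype configurations.  A synthetic-collection
generator with a ground-truth manifest makes every stage testable.
"""

from importlib import resources as _resources

import pandas as _pd

from .io import (
    FilterConfig,
    FilterReport,
    GeneAnnotation,
    GenotypeMatrix,
    MorphometryRecord,
    SNPLocus,
    apply_quality_filters,
    collapse_binary,
    expand_codominant,
    read_dart_report,
    read_gff3,
    read_monthly_climate,
    read_morphometry,
    write_dart_report,
)
from .popgen import (
    DiversitySummary,
    accession_heterozygosity,
    allele_frequencies,
    diversity_summary,
    group_stat_anova,
    locus_stats,
    mutation_spectrum,
    pic,
    sliding_window_profile,
    spectrum_to_loci,
)
from .distance import (
    AMOVAResult,
    DistanceMatrix,
    MantelResult,
    OrdinationResult,
    abs_diff_matrix,
    amova,
    geographic_distance,
    gower_dissimilarity,
    jaccard_distance,
    mantel,
    pca,
    pcoa,
)
from .ecogeo import (
    ExtremeGroups,
    aggregate_climate,
    build_extreme_groups,
    screen_parameters,
)
from .unique_alleles import (
    UniqueAlleleRecord,
    UniqueAlleleSet,
    cluster_records,
    dedupe_union,
    detect_unique_alleles,
    genes_near,
    unique_window_profile,
)
from .morphometry import status_comparison, summarize_morphometry
from .structure_tools import assign_memberships, best_k, evanno_delta_k
from .gpa import GPAResult, consensus_test, gpa, panova, select_dimensions
from .simulate import (
    BARLEY_CHROM_LENGTHS,
    PlantedAlleleSpec,
    SimulationParams,
    expected_detector_output,
    simulate_collection,
)

__version__ = "0.1.0"


def load_reference_spectrum() -> _pd.DataFrame:
    """Published per-chromosome substitution counts for a 63-accession
    barley collection (9737 placed DArTseq loci), used as a worked input."""
    with _resources.files("dartpool.data").joinpath(
        "barley_spectrum_counts.csv"
    ).open() as fh:
        return _pd.read_csv(fh, index_col=0)
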