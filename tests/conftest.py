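import numpy as np
import pandas as pd
import pytest

from dartpool import GenotypeMatrix
from dartpool.simulate import (
    PlantedAlleleSpec,
    SimulationParams,
    simulate_collection,
)


def small_params(**overrides) -> SimulationParams:
    """Scaled-down generating conditions for fast tests."""
    defaults = dict(
        n_landraces=24,
        n_breeding=6,
        n_loci=600,
        n_sites=12,
        year_range=(2000, 2009),
        planted=(
            PlantedAlleleSpec(
                parameter="PDSI", direction="low",
                windows=(
                    ("5H", 370_000_000, 372_000_000),
                    ("6H", 19_000_000, 20_000_000),
                ),
                count=15,
            ),
        ),
        grains_per_accession=20,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def collection():
    """One small synthetic collection shared across tests."""
    return simulate_collection(small_params(), seed=11)


@pytest.fixture(scope="session")
def clean_collection():
    """No missing calls, perfect quality: detector ground truth is exact."""
    return simulate_collection(
        small_params(missing_rate=0.0, low_quality_fraction=0.0), seed=7
    )


def toy_matrix(codes, chroms=None, positions=None, ref=None, alt=None,
               rep_avg=None, call_rate=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a 2-D list (NaN for missing)."""
    codes = np.asarray(codes, dtype=float)
    n_acc, n_loc = codes.shape
    loci = pd.DataFrame(
        {
            "chrom": chroms or ["1H"] * n_loc,
            "pos_bp": positions or list(range(1, n_loc + 1)),
            "ref_allele": ref or ["A"] * n_loc,
            "alt_allele": alt or ["G"] * n_loc,
            "rep_avg": rep_avg or [1.0] * n_loc,
            "call_rate": call_rate or [1.0] * n_loc,
        },
        index=pd.Index([f"L{j + 1}" for j in range(n_loc)], name="locus_id"),
    )
    calls = pd.DataFrame(
        codes,
        index=pd.Index([f"A{i + 1}" for i in range(n_acc)], name="accession_id"),
        columns=loci.index,
    )
    return GenotypeMatrix(calls, loci)
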