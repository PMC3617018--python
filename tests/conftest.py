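import numpy as np
import pandas as pd
import pytest

from chromdiverge.binning import StructureMatrix
from chromdiverge.layout import Chromosome, GenomeLayout


@pytest.fixture
def small_layout():
    return GenomeLayout(
        species_tag="A",
        chromosomes=[
            Chromosome("chr1", 10_000_000, centromere_bp=4_000_000),
            Chromosome("chr2", 5_000_000, centromere_bp=2_000_000),
        ],
    )


def make_matrix(values: dict, species: dict, region_coords: pd.DataFrame | None = None):
    """Build a StructureMatrix from plain dicts for unit tests."""
    vals = pd.DataFrame(values, dtype=float)
    vals.index = pd.Index([f"R{i:04d}" for i in range(len(vals))], name="region_id")
    if region_coords is None:
        n = len(vals)
        region_coords = pd.DataFrame(
            {
                "region_id": vals.index,
                "chrom_A": "chr1",
                "start_A": np.arange(n) * 100_000,
                "end_A": (np.arange(n) + 1) * 100_000,
                "chrom_B": "chr1",
                "start_B": np.arange(n) * 100_000,
                "end_B": (np.arange(n) + 1) * 100_000,
                "overlap_A": 1.0,
                "overlap_B": 1.0,
            }
        )
    datasets = pd.DataFrame(
        {
            "dataset": list(values.keys()),
            "species": [species[k] for k in values.keys()],
            "assay": "generic",
            "cell_type": "generic",
        }
    )
    return StructureMatrix(regions=region_coords, values=vals, datasets=datasets)


@pytest.fixture
def make_matrix_factory():
    return make_matrix


def signal_matrix(
    n_regions: int,
    n_per_species: int,
    effect: float,
    sigma: float,
    frac_divergent: float,
    seed: int,
):
    """Two-species matrix with a known divergent subset (no spatial layout)."""
    rng = np.random.default_rng(seed)
    n_div = int(round(frac_divergent * n_regions))
    truth = np.zeros(n_regions, dtype=int)
    idx = rng.choice(n_regions, size=n_div, replace=False)
    truth[idx] = rng.choice([-1, 1], size=n_div)
    base = rng.choice([-1.0, 1.0], size=n_regions)
    cols = {}
    species = {}
    for s, sign in (("A", 0.5), ("B", -0.5)):
        for j in range(n_per_species):
            name = f"{s}{j}"
            mean = base + truth * sign * effect
            cols[name] = mean + rng.normal(0, sigma, n_regions)
            species[name] = s
    return make_matrix(cols, species), truth


@pytest.fixture
def signal_matrix_factory():
    return signal_matrix
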