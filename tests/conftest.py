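"""Shared fixtures: tiny landscapes, genotype tables and helper builders."""

import numpy as np
import pytest

from paleodiff import (
    BinarySuitabilityRaster,
    CostClass,
    CostClassRaster,
    GenotypeTable,
    LandscapeGrid,
    ScenarioParams,
    SuitabilitySeries,
    two_refugia_scenario,
)


def make_landscape(class_rows, origin_lon=0.5, origin_lat=None, cell_size=1.0):
    """Build (suitability, classes) from a list of rows of CostClass codes."""
    classes = np.array(class_rows, dtype=np.int8)
    n_rows, n_cols = classes.shape
    if origin_lat is None:
        origin_lat = (n_rows - 1) * cell_size / 2.0  # straddle the equator
    grid = LandscapeGrid(n_rows, n_cols, origin_lon, origin_lat, cell_size)
    suitable = classes == int(CostClass.SUITABLE)
    return BinarySuitabilityRaster(grid, suitable), CostClassRaster(grid, classes)


@pytest.fixture
def uniform_3x3():
    """3x3 fully suitable landscape straddling the equator."""
    return make_landscape(np.zeros((3, 3), dtype=int))


@pytest.fixture
def equatorial_1x3():
    """1x3 suitable strip with cell centers on the equator."""
    return make_landscape(np.zeros((1, 3), dtype=int), origin_lat=0.0)


@pytest.fixture
def static_series(uniform_3x3):
    suit, classes = uniform_3x3
    return SuitabilitySeries(steps=[(suit, classes)] * 3)


@pytest.fixture
def small_two_refugia():
    """Scaled-down two-refugia scenario that runs in well under a second."""
    params = ScenarioParams(
        n_rows=8, n_cols=16, refugium_width=3, glacial_steps=10, postglacial_steps=5
    )
    return params, two_refugia_scenario(params)


def make_genotype_table(pop_genos, loci=None):
    """GenotypeTable from {pop: [[(a1, a2) per locus] per individual]}."""
    pops = list(pop_genos)
    n_loci = len(pop_genos[pops[0]][0])
    loci = loci or [f"loc{i + 1}" for i in range(n_loci)]
    genotypes = {}
    individuals = {}
    for pop, inds in pop_genos.items():
        arr = np.array(inds, dtype=int)
        genotypes[pop] = arr.reshape(len(inds), n_loci, 2)
        individuals[pop] = [f"{pop}_{i + 1}" for i in range(len(inds))]
    return GenotypeTable(pops, loci, individuals, genotypes)


@pytest.fixture
def fixed_alleles_table():
    """Two populations fixed for alternative alleles at one locus, n=10 each."""
    return make_genotype_table(
        {"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10}
    )
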