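"""Parametric synthetic study systems: landscapes and genotype tables.

``two_refugia_scenario`` emulates the canonical glacial setting the
simulator is built for: two suitable refugial blocks kept apart by an ice
barrier during the glacial phase, then joined by a suitable corridor after
deglaciation. The grid defaults to 30 x 30 cells of 1 degree centered on
the equator, so cell-to-cell distances are ~111 km and km-scale dispersal
parameters keep their real-world meaning.

``synthetic_genotypes`` uses a hierarchical (Balding-Nichols style) allele
frequency model: population frequencies are Dirichlet perturbations of a
common ancestral frequency with variance set by ``divergence_level``, whose
expected FST equals that level. It provides statistical structure for
testing the empirical distance estimators without coalescent machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from paleodiff.grid import (
    BinarySuitabilityRaster,
    CostClass,
    CostClassRaster,
    LandscapeGrid,
    SuitabilitySeries,
)
from paleodiff.popgen import GenotypeTable

__all__ = [
    "ScenarioParams",
    "two_refugia_scenario",
    "random_scenario",
    "synthetic_genotypes",
    "write_genepop",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Geometry and duration of the two-refugia glacial cycle.

    Two suitable blocks of ``refugium_width`` columns sit at the west and
    east edges; the columns between them are GLACIER for ``glacial_steps``
    steps, then turn suitable (the corridor) for ``postglacial_steps``
    steps. ``corridor_rows`` restricts the corridor to a row range
    (start, stop); None opens the full band.
    """

    n_rows: int = 30
    n_cols: int = 30
    cell_size: float = 1.0
    origin_lon: float = 0.5
    origin_lat: float = 14.5
    glacial_steps: int = 100
    postglacial_steps: int = 50
    refugium_width: int = 8
    corridor_rows: tuple[int, int] | None = None
    step_years: float = 100.0

    def __post_init__(self) -> None:
        if self.glacial_steps < 1 or self.postglacial_steps < 0:
            raise ValueError("need >= 1 glacial and >= 0 postglacial steps")
        if self.refugium_width < 1 or 2 * self.refugium_width >= self.n_cols:
            raise ValueError(
                "refugia overlap: 2 * refugium_width must be < n_cols so a barrier remains"
            )
        if self.corridor_rows is not None:
            lo, hi = self.corridor_rows
            if not (0 <= lo < hi <= self.n_rows):
                raise ValueError("corridor_rows outside grid")

    @property
    def grid(self) -> LandscapeGrid:
        return LandscapeGrid(
            self.n_rows, self.n_cols, self.origin_lon, self.origin_lat, self.cell_size
        )


def two_refugia_scenario(params: ScenarioParams | None = None) -> SuitabilitySeries:
    """Deterministic dynamic landscape: isolation phase, then contact phase."""
    params = params or ScenarioParams()
    grid = params.grid
    rw = params.refugium_width
    refugia = np.zeros(grid.shape, dtype=bool)
    refugia[:, :rw] = True
    refugia[:, grid.n_cols - rw :] = True
    barrier = np.zeros(grid.shape, dtype=bool)
    barrier[:, rw : grid.n_cols - rw] = True

    glacial_classes = np.full(grid.shape, int(CostClass.UNSUITABLE_LAND), dtype=np.int8)
    glacial_classes[refugia] = int(CostClass.SUITABLE)
    glacial_classes[barrier] = int(CostClass.GLACIER)

    post_suit = refugia.copy()
    if params.corridor_rows is None:
        post_suit |= barrier
    else:
        lo, hi = params.corridor_rows
        corridor = barrier.copy()
        corridor[:lo, :] = False
        corridor[hi:, :] = False
        post_suit |= corridor
    post_classes = np.full(grid.shape, int(CostClass.UNSUITABLE_LAND), dtype=np.int8)
    post_classes[post_suit] = int(CostClass.SUITABLE)

    glacial = (
        BinarySuitabilityRaster(grid, refugia),
        CostClassRaster(grid, glacial_classes),
    )
    postglacial = (
        BinarySuitabilityRaster(grid, post_suit),
        CostClassRaster(grid, post_classes),
    )
    steps = [glacial] * params.glacial_steps + [postglacial] * params.postglacial_steps
    return SuitabilitySeries(steps=steps, step_years=params.step_years)


def random_scenario(
    grid: LandscapeGrid,
    n_steps: int,
    suitability_fraction: float,
    seed: int,
    persistence: float = 0.8,
) -> SuitabilitySeries:
    """Random dynamic landscape for property tests.

    Each cell is suitable with probability ``suitability_fraction``;
    between consecutive steps a cell keeps its state with probability
    ``persistence`` and is resampled otherwise. Unsuitable cells get a
    random class among unsuitable land / glacier / sea.
    """
    if not 0.0 < suitability_fraction <= 1.0:
        raise ValueError("suitability_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    steps = []
    suit = rng.random(grid.shape) < suitability_fraction
    for _ in range(n_steps):
        classes = rng.integers(1, 4, size=grid.shape).astype(np.int8)
        classes[suit] = int(CostClass.SUITABLE)
        steps.append(
            (BinarySuitabilityRaster(grid, suit.copy()), CostClassRaster(grid, classes))
        )
        keep = rng.random(grid.shape) < persistence
        resampled = rng.random(grid.shape) < suitability_fraction
        suit = np.where(keep, suit, resampled)
    return SuitabilitySeries(steps=steps)


def synthetic_genotypes(
    n_pops: int = 4,
    n_loci: int = 16,
    n_ind: int = 30,
    divergence_level: float = 0.2,
    seed: int = 0,
    n_alleles: int = 8,
) -> GenotypeTable:
    """Diploid genotypes with expected pairwise FST ~ ``divergence_level``.

    Ancestral allele frequencies per locus come from a flat Dirichlet;
    population frequencies from Dirichlet(ancestral * (1 - F) / F) with
    F = divergence_level (F = 0 copies the ancestral frequencies, F -> 1
    fixes each population for one allele).
    """
    if not 0.0 <= divergence_level <= 1.0:
        raise ValueError("divergence_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pops = [f"pop{p + 1}" for p in range(n_pops)]
    loci = [f"loc{l + 1}" for l in range(n_loci)]
    codes = np.arange(1, n_alleles + 1)
    genotypes: dict[str, np.ndarray] = {p: np.zeros((n_ind, n_loci, 2), dtype=int) for p in pops}
    F = divergence_level
    for l in range(n_loci):
        ancestral = rng.dirichlet(np.ones(n_alleles))
        for pop in pops:
            if F == 0.0:
                p_freq = ancestral
            elif F >= 0.999:
                p_freq = np.zeros(n_alleles)
                p_freq[rng.choice(n_alleles, p=ancestral)] = 1.0
            else:
                p_freq = rng.dirichlet(np.maximum(ancestral, 1e-9) * (1.0 - F) / F)
            draws = rng.choice(codes, size=(n_ind, 2), p=p_freq / p_freq.sum())
            genotypes[pop][:, l, :] = draws
    individuals = {p: [f"{p}_ind{i + 1}" for i in range(n_ind)] for p in pops}
    return GenotypeTable(pops, loci, individuals, genotypes)


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "synthetic genotypes") -> None:
    """Write a 2-digit (or 3-digit if needed) Genepop file."""
    max_code = max(
        (int(g[g >= 0].max(initial=0)) for g in table.genotypes.values()), default=0
    )
    width = 3 if max_code > 99 else 2
    if max_code >= 10**width:
        raise ValueError("allele codes too large for Genepop encoding")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for pop in table.populations:
            fh.write("Pop\n")
            g = table.genotypes[pop]
            for i, ind in enumerate(table.individuals[pop]):
                tokens = []
                for l in range(len(table.loci)):
                    a1, a2 = g[i, l]
                    if a1 < 0 or a2 < 0:
                        a1 = a2 = 0
                    tokens.append(f"{a1:0{width}d}{a2:0{width}d}")
                fh.write(f"{ind} , " + " ".join(tokens) + "\n")
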