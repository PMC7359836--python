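"""Empirical population genetics: allele frequencies, chord distance, FST.

Works on diploid multi-locus genotype tables (microsatellite-style integer
allele codes) read from Genepop files or a long CSV. Pairwise population
differentiation is measured two ways:

* Cavalli-Sforza & Edwards chord distance Dc, with the 2/(pi*L)
  normalization, bounded by 2*sqrt(2)/pi;
* Weir & Cockerham's (1984) theta, the variance-components FST estimator,
  combined across loci as a ratio of summed components.

Missing data are handled by available-allele counting: a population x locus
with zero scored alleles is undefined and that locus is dropped for pairs
involving it, but individuals are never dropped globally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from paleodiff.matrixio import DistanceMatrix

__all__ = [
    "GenotypeTable",
    "AlleleFreqs",
    "read_genotypes",
    "allele_freqs",
    "chord_distance",
    "fst_weir_cockerham",
    "CHORD_MAX",
]

MISSING = -1
#: upper bound of the chord distance: populations fixed for different alleles
CHORD_MAX = 2.0 * math.sqrt(2.0) / math.pi


@dataclass
class GenotypeTable:
    """Diploid genotypes: per population an (n_ind, n_loci, 2) int array.

    Allele codes are arbitrary positive integers; ``MISSING`` (-1) marks an
    unscored genotype (both allele slots).
    """

    populations: list[str]
    loci: list[str]
    individuals: dict[str, list[str]]
    genotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for pop in self.populations:
            g = np.asarray(self.genotypes[pop], dtype=int)
            if g.shape[1:] != (len(self.loci), 2):
                raise ValueError(f"population {pop}: genotype array shape {g.shape} invalid")
            self.genotypes[pop] = g

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def read_genotypes(path: str | Path, dialect: str = "genepop") -> GenotypeTable:
    """Read a Genepop (2- or 3-digit) or long CSV genotype file.

    The long CSV has columns population, individual, locus, allele1, allele2
    with 0/empty meaning missing. Genepop population labels are taken from
    the first individual of each population block.
    """
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "long_csv":
        return _read_long_csv(path)
    raise ValueError("dialect must be 'genepop' or 'long_csv'")


def _read_genepop(path: str | Path) -> GenotypeTable:
    from Bio.PopGen import GenePop

    with open(path) as fh:
        record = GenePop.read(fh)
    loci = list(record.loci_list)
    if len(record.populations) < 2:
        raise ValueError("Genepop file must contain at least two populations")
    populations: list[str] = []
    individuals: dict[str, list[str]] = {}
    genotypes: dict[str, np.ndarray] = {}
    for p, pop in enumerate(record.populations):
        label = str(pop[0][0]).strip().rstrip(",") or f"pop{p + 1}"
        if label in populations:
            label = f"{label}_{p + 1}"
        g = np.full((len(pop), len(loci), 2), MISSING, dtype=int)
        names = []
        for i, (name, alleles) in enumerate(pop):
            names.append(str(name).strip().rstrip(","))
            if len(alleles) != len(loci):
                raise ValueError(f"individual {name}: {len(alleles)} genotypes for {len(loci)} loci")
            for l, geno in enumerate(alleles):
                if geno is None:
                    continue
                if len(geno) != 2:
                    raise ValueError(f"individual {name}, locus {loci[l]}: not diploid")
                a1, a2 = geno
                if a1 in (None, 0) or a2 in (None, 0):
                    continue  # 0/000 allele code = missing genotype
                g[i, l] = (int(a1), int(a2))
        populations.append(label)
        individuals[label] = names
        genotypes[label] = g
    return GenotypeTable(populations, loci, individuals, genotypes)


def _read_long_csv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"population": str, "individual": str, "locus": str})
    required = {"population", "individual", "locus", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"long CSV needs columns {sorted(required)}")
    populations = list(dict.fromkeys(df["population"]))
    if len(populations) < 2:
        raise ValueError("genotype table must contain at least two populations")
    loci = list(dict.fromkeys(df["locus"]))
    loc_pos = {l: i for i, l in enumerate(loci)}
    individuals: dict[str, list[str]] = {}
    genotypes: dict[str, np.ndarray] = {}
    for pop, sub in df.groupby("population", sort=False):
        names = list(dict.fromkeys(sub["individual"]))
        ind_pos = {n: i for i, n in enumerate(names)}
        g = np.full((len(names), len(loci), 2), MISSING, dtype=int)
        for row in sub.itertuples(index=False):
            a1 = 0 if pd.isna(row.allele1) else int(row.allele1)
            a2 = 0 if pd.isna(row.allele2) else int(row.allele2)
            if a1 > 0 and a2 > 0:
                g[ind_pos[row.individual], loc_pos[row.locus]] = (a1, a2)
        individuals[str(pop)] = names
        genotypes[str(pop)] = g
    return GenotypeTable([str(p) for p in populations], loci, individuals, genotypes)


@dataclass
class AlleleFreqs:
    """Per population x locus allele frequencies over non-missing copies.

    ``freqs[pop][locus]`` maps allele code -> frequency; ``n_alleles`` holds
    the number of scored allele copies (2 x scored individuals).
    ``undefined`` lists (pop, locus) pairs with zero scored alleles.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    n_alleles: dict[str, dict[str, int]]
    undefined: list[tuple[str, str]]


def allele_freqs(table: GenotypeTable) -> AlleleFreqs:
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    n_alleles: dict[str, dict[str, int]] = {}
    undefined: list[tuple[str, str]] = []
    for pop in table.populations:
        g = table.genotypes[pop]
        freqs[pop] = {}
        n_alleles[pop] = {}
        for l, locus in enumerate(table.loci):
            alleles = g[:, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            n_alleles[pop][locus] = int(alleles.size)
            if alleles.size == 0:
                undefined.append((pop, locus))
                freqs[pop][locus] = {}
                continue
            codes, counts = np.unique(alleles, return_counts=True)
            freqs[pop][locus] = {int(a): c / alleles.size for a, c in zip(codes, counts)}
    return AlleleFreqs(table.populations, table.loci, freqs, n_alleles, undefined)


def chord_distance(freqs: AlleleFreqs) -> DistanceMatrix:
    """Pairwise Cavalli-Sforza chord distance.

    Dc(X, Y) = 2/(pi*L) * sum over shared defined loci of
    sqrt(2 * (1 - sum_a sqrt(x_a * y_a))). Loci undefined in either
    population drop out of L for that pair.
    """
    pops = freqs.populations
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            n_loci = 0
            for locus in freqs.loci:
                x = freqs.freqs[pops[i]][locus]
                y = freqs.freqs[pops[j]][locus]
                if not x or not y:
                    continue
                cos = sum(math.sqrt(x[a] * y[a]) for a in set(x) & set(y))
                total += math.sqrt(2.0 * max(0.0, 1.0 - cos))
                n_loci += 1
            if n_loci == 0:
                raise ValueError(f"no shared defined loci for pair ({pops[i]}, {pops[j]})")
            values[i, j] = values[j, i] = 2.0 / (math.pi * n_loci) * total
    return DistanceMatrix(labels=list(pops), values=values)


def fst_weir_cockerham(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise multi-locus Weir & Cockerham (1984) theta.

    For each population pair, the a (among-population), b (among individuals
    within populations) and c (within-individual) variance components are
    computed per locus and allele from sample sizes, allele frequencies and
    observed heterozygote frequencies, then summed across alleles and loci:
    theta = sum(a) / sum(a + b + c). Negative estimates are retained.
    """
    pops = table.populations
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _theta_pair(
                table.genotypes[pops[i]], table.genotypes[pops[j]], len(table.loci)
            )
    return DistanceMatrix(labels=list(pops), values=values)


def _theta_pair(g1: np.ndarray, g2: np.ndarray, n_loci: int) -> float:
    r = 2  # number of populations
    num = 0.0
    den = 0.0
    any_locus = False
    for l in range(n_loci):
        per_pop = []
        for g in (g1, g2):
            gl = g[:, l, :]
            scored = gl[:, 0] != MISSING
            gl = gl[scored]
            if gl.shape[0] == 0:
                per_pop = []
                break
            per_pop.append(gl)
        if not per_pop:
            continue  # locus unusable for this pair
        any_locus = True
        ns = np.array([g.shape[0] for g in per_pop], dtype=float)  # individuals
        alleles = np.unique(np.concatenate([g.ravel() for g in per_pop]))
        nbar = ns.mean()
        if nbar <= 1 or alleles.size < 2:
            continue  # monomorphic locus contributes nothing
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        for a in alleles:
            p = np.array([np.mean(g == a) for g in per_pop])  # allele freq per pop
            h = np.array(  # observed frequency of heterozygotes carrying a
                [np.mean((g == a).sum(axis=1) == 1) for g in per_pop]
            )
            pbar = (ns * p).sum() / (r * nbar)
            s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * h).sum() / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a_comp = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
            b_comp = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_comp = hbar / 2.0
            num += a_comp
            den += a_comp + b_comp + c_comp
    if not any_locus:
        raise ValueError("population pair shares no usable locus")
    if den == 0.0:
        return 0.0
    return num / den
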