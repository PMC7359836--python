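"""Comparison of simulated and empirical genetic distance matrices.

Sampling sites are mapped onto occupied simulation cells within a great-
circle buffer (200 km by default); populations present in only one of the
two matrices are dropped. The matched matrices are then ordinated with
principal coordinate analysis (PCoA), summarized as UPGMA dendrograms, and
correlated with a Mantel permutation test on Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from paleodiff.grid import LandscapeGrid, _haversine_km
from paleodiff.matrixio import DistanceMatrix

__all__ = [
    "PCoAResult",
    "MantelResult",
    "assign_sites_to_cells",
    "pcoa",
    "upgma_newick",
    "mantel_spearman",
    "pcoa_colors",
]


def assign_sites_to_cells(
    sites: pd.DataFrame,
    occupied: np.ndarray,
    grid: LandscapeGrid,
    buffer_km: float = 200.0,
) -> dict[str, int]:
    """Map each site to its nearest occupied cell center within ``buffer_km``.

    ``sites`` needs columns site, lon, lat. Sites with no occupied cell in
    range stay unassigned (absent from the result) and are meant to be
    excluded downstream. Distance ties resolve to the lowest cell id.
    """
    required = {"site", "lon", "lat"}
    if not required <= set(sites.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    occupied = np.sort(np.asarray(occupied, dtype=np.int64))
    if occupied.size == 0:
        return {}
    cell_lon, cell_lat = grid.cell_center(occupied)
    out: dict[str, int] = {}
    for row in sites.itertuples(index=False):
        dist = _haversine_km(float(row.lon), float(row.lat), cell_lon, cell_lat)
        best = int(np.argmin(dist))  # first minimum -> lowest cell id
        if dist[best] <= buffer_km:
            out[str(row.site)] = int(occupied[best])
    return out


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` has one column per positive eigenvalue (descending);
    ``eigenvalues`` keeps the full spectrum, negatives included, and
    ``pct_variance`` is each positive axis's share of the positive
    eigenvalue total (no Cailliez/Lingoes correction is applied).
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinate analysis via Gower double-centering of -D^2/2."""
    D = dm.values
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(dm)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        labels=list(dm.labels), coordinates=coords, eigenvalues=eigval, pct_variance=pct
    )


def _fmt_branch(x: float) -> str:
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "n" not in s:
        s += ".0"
    return s


def upgma_newick(dm: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) ultrametric dendrogram as a Newick string.

    Node heights are half the merge distance; ties break alphabetically by
    label, and children of each node are ordered by their smallest leaf
    label.
    """
    if len(dm) < 2:
        raise ValueError("need at least 2 labels for a tree")
    order = np.argsort(np.asarray(dm.labels))
    labels = [dm.labels[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    Z = linkage(squareform(values, checks=False), method="average")

    n = len(labels)
    # node -> (newick string, height, smallest leaf label)
    nodes: dict[int, tuple[str, float, str]] = {
        i: (labels[i], 0.0, labels[i]) for i in range(n)
    }
    for k, (a, b, dist, _) in enumerate(Z):
        ca, cb = nodes.pop(int(a)), nodes.pop(int(b))
        height = dist / 2.0
        children = sorted([ca, cb], key=lambda c: c[2])
        parts = ",".join(f"{c[0]}:{_fmt_branch(height - c[1])}" for c in children)
        nodes[n + k] = (f"({parts})", height, children[0][2])
    (tree, _, _), = nodes.values()
    return tree + ";"


def nj_newick(dm: DistanceMatrix) -> str:
    """Neighbor-joining alternative to UPGMA (unrooted, non-ultrametric)."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(dm.values, ids=dm.labels))
    return str(tree).strip()


@dataclass
class MantelResult:
    """Mantel permutation test of two distance matrices.

    ``rho`` is Spearman's correlation of the strictly-lower-triangle
    entries; the null permutes rows/columns of the second matrix jointly;
    ``p_value`` uses the (exceedances + 1) / (n_perm + 1) convention on
    |rho|. ``r_squared`` is the squared Pearson correlation of the same two
    vectors, reported as a convenience effect size.
    """

    rho: float
    p_value: float
    n_permutations: int
    seed: int
    n: int
    r_squared: float


def mantel_spearman(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test with Spearman correlation on the common labels of D1, D2."""
    common = [lab for lab in D1.labels if lab in set(D2.labels)]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common labels; need >= 3")
    A = D1.submatrix(common).values
    B = D2.submatrix(common).values
    n = len(common)
    tri = np.tril_indices(n, k=-1)
    v1 = A[tri]
    if np.all(v1 == v1[0]) or np.all(B[tri] == B[tri][0]):
        raise ValueError("degenerate (constant) distance matrix")
    rho = float(spearmanr(v1, B[tri]).statistic)
    r2 = float(pearsonr(v1, B[tri]).statistic ** 2)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = spearmanr(v1, B[np.ix_(perm, perm)][tri]).statistic
        if abs(rp) >= abs(rho) - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(rho=rho, p_value=p, n_permutations=n_perm, seed=seed, n=n, r_squared=r2)


def pcoa_colors(result: PCoAResult) -> dict[str, tuple[float, float, float]]:
    """Deterministic RGB per label from the first two PCoA axes.

    Axis 1 drives a red-blue gradient, axis 2 perturbs the green channel
    around mid-gray; axes are min-max scaled so colors are invariant to
    global translation of the configuration.
    """
    n = len(result.labels)
    coords = result.coordinates
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])

    def scaled(axis: np.ndarray) -> np.ndarray:
        span = axis.max() - axis.min()
        if span <= 0:
            return np.full(n, 0.5)
        return (axis - axis.min()) / span

    a1 = scaled(coords[:, 0])
    a2 = scaled(coords[:, 1])
    green = (0.5 + a2) / 2.0
    return {
        lab: (float(a1[i]), float(green[i]), float(1.0 - a1[i]))
        for i, lab in enumerate(result.labels)
    }
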