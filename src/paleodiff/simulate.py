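"""Forward simulation of pairwise divergence over a dynamic landscape.

The simulated agent is the population occupying one grid cell. Per time
step, in a fixed order:

1. extinction — populations whose cell turned unsuitable are removed;
2. colonization — every suitable empty cell reachable from an occupied
   source (least-cost path < the source's per-step dispersal distance) is
   occupied and inherits the divergence row of its cheapest source;
3. connection + divergence update — occupied cells are linked where
   per-step dispersal exceeds the least-cost path; pairs in the same
   connected component lose ``delta_flow`` divergence units (floored at 0,
   gene flow), pairs in different components gain
   ``drift_multiplier * delta_flow`` units (drift).

Divergence is an abstract beta-diversity bookkeeping quantity: no alleles,
mutation or population sizes are modeled. Gene flow homogenizes whole
connected components (not only directly linked pairs), so persistent
clusters relax to exactly zero internal divergence.

A burn-in repeats the oldest landscape for ``burn_in_steps`` cycles before
the dynamic phase so that populations isolated in glacial refugia start the
dynamic run already differentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from paleodiff.connectivity import (
    ConnectionGraph,
    CostDistanceMatrix,
    connection_edges,
    least_cost_matrix,
)
from paleodiff.dispersal import DispersalKernel
from paleodiff.grid import (
    BinarySuitabilityRaster,
    CostClassRaster,
    CostParams,
    SuitabilitySeries,
    build_cost_graph,
)

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "GlobalExtinctionError",
    "initialize_state",
    "apply_extinction",
    "colonize",
    "update_divergence",
    "burn_in",
    "run_simulation",
]


class GlobalExtinctionError(RuntimeError):
    """Raised when no occupied cell survives a suitability change."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(f"global extinction at step {step_index}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    delta_flow             divergence units removed per connected step
    drift_multiplier       accumulation : reduction ratio (drift runs this
                           many times faster than gene flow)
    burn_in_steps          repeats of the oldest landscape before the run
    step_years             years represented by one landscape step
    dispersal_threshold_years
                           years of movement allowed when comparing a
                           km/year draw against a least-cost path
                           (None -> step_years)
    connection_rule        'max' (either population reaches) or 'min'
    redraw_each_step       draw fresh per-cell dispersal every step instead
                           of once per cell
    """

    delta_flow: float = 1.0
    drift_multiplier: float = 3.0
    burn_in_steps: int = 50
    step_years: float = 100.0
    dispersal_threshold_years: float | None = None
    connection_rule: str = "max"
    neighborhood: int = 8
    seed: int = 0
    cost_params: CostParams = field(default_factory=CostParams)
    kernel: DispersalKernel = field(default_factory=DispersalKernel)
    redraw_each_step: bool = False

    def __post_init__(self) -> None:
        if self.delta_flow <= 0:
            raise ValueError("delta_flow must be positive")
        if self.drift_multiplier <= 0:
            raise ValueError("drift_multiplier must be positive")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")

    @property
    def threshold_years(self) -> float:
        return self.step_years if self.dispersal_threshold_years is None else self.dispersal_threshold_years


@dataclass
class SimState:
    """Occupied cells, their dispersal draws and the divergence matrix D.

    ``rng_state`` is the opaque reproducibility payload: one dispersal draw
    (km/year) per grid cell, fixed at initialization, so a cell keeps its
    draw for as long as it stays occupied and colonization order cannot
    perturb the stream.
    """

    step_index: int
    occupied: np.ndarray  # sorted linear cell ids
    D: np.ndarray  # symmetric divergence matrix over occupied cells
    rng_state: np.ndarray  # per-grid-cell dispersal draw, km/year

    @property
    def dispersal_km_yr(self) -> np.ndarray:
        return self.rng_state[self.occupied]

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.size)

    def check_invariants(self) -> None:
        assert np.array_equal(self.occupied, np.sort(self.occupied))
        assert self.D.shape == (self.n_occupied, self.n_occupied)
        assert np.allclose(self.D, self.D.T)
        assert np.all(np.diag(self.D) == 0.0)
        assert np.all(self.D >= 0.0)


@dataclass
class SimResult:
    final_state: SimState
    snapshots: list[tuple[int, np.ndarray, np.ndarray]]  # (step, occupied, component labels)
    D_snapshots: dict[int, tuple[np.ndarray, np.ndarray]]  # step -> (occupied, D)
    config: SimConfig
    occupied_counts: list[int]
    component_counts: list[int]


def _draw_grid_dispersal(n_cells: int, config: SimConfig, seed: int) -> np.ndarray:
    u = np.random.default_rng(seed).random(n_cells)
    return np.asarray(config.kernel.ppf(u))


def initialize_state(series: SuitabilitySeries, config: SimConfig) -> SimState:
    """Occupy every suitable cell of the oldest step with zero divergence."""
    suit, _ = series.steps[0]
    occupied = suit.suitable_cells()
    if occupied.size == 0:
        raise ValueError("empty initial landscape: oldest step has no suitable cell")
    draws = _draw_grid_dispersal(series.grid.n_cells, config, config.seed)
    n = occupied.size
    return SimState(step_index=0, occupied=occupied, D=np.zeros((n, n)), rng_state=draws)


def apply_extinction(state: SimState, suitability: BinarySuitabilityRaster) -> SimState:
    """Remove populations whose cell turned unsuitable (rows/cols drop from D)."""
    flat = suitability.suitable.ravel()
    keep = flat[state.occupied]
    if keep.all():
        return state
    idx = np.flatnonzero(keep)
    return replace(
        state,
        occupied=state.occupied[idx],
        D=state.D[np.ix_(idx, idx)],
    )


def colonize(
    state: SimState,
    costD: CostDistanceMatrix,
    suitable_unoccupied: np.ndarray,
    per_step_km: np.ndarray,
) -> SimState:
    """Occupy every reachable suitable cell; colonists inherit divergence.

    A target is colonized iff some occupied source s has LCP(s, target)
    strictly below s's per-step dispersal distance. The colonist copies the
    divergence row of its minimal-cost source (tie -> lowest source cell
    id), so two same-step colonists inherit their sources' divergence and a
    colonist is at divergence 0 from its own source.
    """
    targets = np.setdiff1d(np.asarray(suitable_unoccupied, dtype=np.int64), state.occupied)
    if targets.size == 0 or state.n_occupied == 0:
        return state
    occ_idx = costD.index_of(state.occupied)
    tgt_idx = costD.index_of(targets)
    lcp = costD.values[np.ix_(occ_idx, tgt_idx)]
    reach = lcp < np.asarray(per_step_km, dtype=float)[:, None]
    colonizable = reach.any(axis=0)
    if not colonizable.any():
        return state
    new_cells = targets[colonizable]
    masked = np.where(reach[:, colonizable], lcp[:, colonizable], np.inf)
    # sources within float round-off of the cheapest count as tied; the first
    # tied row wins, and occupied is sorted, so ties resolve to the lowest
    # source cell id
    best = masked.min(axis=0)
    tied = masked <= best * (1.0 + 1e-9) + 1e-9
    src_pos = tied.argmax(axis=0)

    occupied_new = np.concatenate([state.occupied, new_cells])
    order = np.argsort(occupied_new, kind="stable")
    # per new-order cell: position in the OLD occupied array whose D row it takes
    src_of = np.concatenate([np.arange(state.n_occupied), src_pos])[order]
    D_new = state.D[np.ix_(src_of, src_of)].copy()
    np.fill_diagonal(D_new, 0.0)
    return replace(state, occupied=occupied_new[order], D=D_new)


def update_divergence(state: SimState, component_labels: np.ndarray, config: SimConfig) -> SimState:
    """Drift between components, gene flow (floored at zero) within them."""
    labels = np.asarray(component_labels)
    if labels.shape != state.occupied.shape:
        raise ValueError("component labels must align with occupied cells")
    same = labels[:, None] == labels[None, :]
    D = np.where(
        same,
        np.maximum(state.D - config.delta_flow, 0.0),
        state.D + config.drift_multiplier * config.delta_flow,
    )
    np.fill_diagonal(D, 0.0)
    return replace(state, D=D)


class _LcpCache:
    """Memoize least-cost matrices per unique (suitability, classes) raster pair."""

    def __init__(self, config: SimConfig):
        self.config = config
        self._store: dict[bytes, CostDistanceMatrix] = {}

    def get(self, suit: BinarySuitabilityRaster, classes: CostClassRaster) -> CostDistanceMatrix:
        key = suit.suitable.tobytes() + classes.classes.tobytes()
        if key not in self._store:
            graph = build_cost_graph(
                suit, classes, self.config.cost_params, self.config.neighborhood
            )
            self._store[key] = least_cost_matrix(graph, suit.suitable_cells())
        return self._store[key]


def _step_cycle(
    state: SimState,
    suit: BinarySuitabilityRaster,
    classes: CostClassRaster,
    config: SimConfig,
    cache: _LcpCache,
) -> tuple[SimState, ConnectionGraph]:
    """Colonization, connection and divergence update on one landscape."""
    costD = cache.get(suit, classes)
    years = config.threshold_years
    per_step_km = state.dispersal_km_yr * years
    state = colonize(state, costD, suit.suitable_cells(), per_step_km)
    conn = connection_edges(
        costD.submatrix(state.occupied), state.dispersal_km_yr * years, config.connection_rule
    )
    state = update_divergence(state, conn.component_label, config)
    return state, conn


def burn_in(
    state: SimState,
    oldest_step: tuple[BinarySuitabilityRaster, CostClassRaster],
    config: SimConfig,
    cache: _LcpCache | None = None,
) -> SimState:
    """Repeat the frozen oldest landscape for ``burn_in_steps`` full cycles."""
    cache = cache or _LcpCache(config)
    suit, classes = oldest_step
    for _ in range(config.burn_in_steps):
        state, _ = _step_cycle(state, suit, classes, config, cache)
    return state


def run_simulation(
    series: SuitabilitySeries,
    config: SimConfig,
    snapshot_steps: list[int] | None = None,
    record_D_steps: list[int] | None = None,
    check_invariants: bool = False,
) -> SimResult:
    """Burn-in followed by the dynamic landscape steps, oldest to newest.

    ``snapshot_steps``/``record_D_steps`` select dynamic step indices at
    which occupancy + component labels / full D copies are kept (None for
    snapshots keeps every step). Deterministic for a fixed config + seed.
    """
    state = initialize_state(series, config)
    cache = _LcpCache(config)
    state = burn_in(state, series.steps[0], config, cache)

    snapshots: list[tuple[int, np.ndarray, np.ndarray]] = []
    D_snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    occupied_counts: list[int] = []
    component_counts: list[int] = []
    for t, (suit, classes) in enumerate(series.steps):
        if config.redraw_each_step:
            seed = np.random.default_rng([config.seed, t + 1]).integers(2**31)
            state = replace(
                state, rng_state=_draw_grid_dispersal(series.grid.n_cells, config, int(seed))
            )
        state = apply_extinction(state, suit)
        if state.n_occupied == 0:
            raise GlobalExtinctionError(t)
        state, conn = _step_cycle(state, suit, classes, config, cache)
        state = replace(state, step_index=t)
        if check_invariants:
            state.check_invariants()
        occupied_counts.append(state.n_occupied)
        component_counts.append(len(np.unique(conn.component_label)))
        if snapshot_steps is None or t in snapshot_steps:
            snapshots.append((t, state.occupied.copy(), conn.component_label.copy()))
        if record_D_steps is not None and t in record_D_steps:
            D_snapshots[t] = (state.occupied.copy(), state.D.copy())
    return SimResult(
        final_state=state,
        snapshots=snapshots,
        D_snapshots=D_snapshots,
        config=config,
        occupied_counts=occupied_counts,
        component_counts=component_counts,
    )
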