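"""The divergence simulator: bookkeeping rules, burn-in, full runs."""

import numpy as np
import pytest

from paleodiff import (
    BinarySuitabilityRaster,
    CostClassRaster,
    DispersalKernel,
    GlobalExtinctionError,
    ScenarioParams,
    SimConfig,
    SimState,
    SuitabilitySeries,
    apply_extinction,
    build_cost_graph,
    burn_in,
    colonize,
    initialize_state,
    least_cost_matrix,
    run_simulation,
    two_refugia_scenario,
    update_divergence,
)
from tests.conftest import make_landscape


def pair_state(d_between=0.0):
    """Minimal two-population state on cells 0 and 1."""
    D = np.array([[0.0, d_between], [d_between, 0.0]])
    return SimState(step_index=0, occupied=np.array([0, 1]), D=D, rng_state=np.ones(4))


class TestInitialize:
    def test_occupies_oldest_suitable_cells(self, static_series):
        cfg = SimConfig(seed=1)
        state = initialize_state(static_series, cfg)
        assert state.n_occupied == 9
        assert np.all(state.D == 0.0) and state.D.shape == (9, 9)
        assert state.dispersal_km_yr.shape == (9,)

    def test_same_seed_same_state(self, static_series):
        s1 = initialize_state(static_series, SimConfig(seed=4))
        s2 = initialize_state(static_series, SimConfig(seed=4))
        assert np.array_equal(s1.dispersal_km_yr, s2.dispersal_km_yr)

    def test_empty_initial_landscape_rejected(self):
        suit, classes = make_landscape([[1, 1]])
        series = SuitabilitySeries(steps=[(suit, classes)])
        with pytest.raises(ValueError, match="empty initial landscape"):
            initialize_state(series, SimConfig())


class TestExtinction:
    def test_unchanged_when_suitability_unchanged(self, static_series):
        state = initialize_state(static_series, SimConfig(seed=0))
        after = apply_extinction(state, static_series.steps[0][0])
        assert after is state

    def test_unsuitable_cell_drops_row_and_column(self, static_series):
        state = initialize_state(static_series, SimConfig(seed=0))
        state.D[:] = np.arange(81).reshape(9, 9)
        suit = np.ones((3, 3), dtype=bool)
        suit[0, 0] = False
        after = apply_extinction(state, BinarySuitabilityRaster(static_series.grid, suit))
        assert after.n_occupied == 8
        assert 0 not in after.occupied
        assert np.array_equal(after.D, state.D[1:, 1:])

    def test_total_loss_empties_state(self, static_series):
        state = initialize_state(static_series, SimConfig(seed=0))
        none = BinarySuitabilityRaster(static_series.grid, np.zeros((3, 3), dtype=bool))
        assert apply_extinction(state, none).n_occupied == 0


class TestColonize:
    def _line_costd(self, n=4):
        suit, classes = make_landscape(np.zeros((1, n), dtype=int), origin_lat=0.0)
        graph = build_cost_graph(suit, classes)
        return suit, least_cost_matrix(graph, np.arange(n))

    def test_colonist_at_zero_divergence_from_source(self):
        suit, costd = self._line_costd(2)
        state = SimState(0, np.array([0]), np.zeros((1, 1)), rng_state=np.ones(2))
        after = colonize(state, costd, suit.suitable_cells(), per_step_km=np.array([150.0]))
        assert after.occupied.tolist() == [0, 1]
        assert after.D[0, 1] == 0.0

    def test_out_of_range_target_not_colonized(self):
        suit, costd = self._line_costd(2)
        state = SimState(0, np.array([0]), np.zeros((1, 1)), rng_state=np.ones(2))
        after = colonize(state, costd, suit.suitable_cells(), per_step_km=np.array([100.0]))
        assert after.occupied.tolist() == [0]

    def test_two_colonists_inherit_their_sources_divergence(self):
        suit, costd = self._line_costd(4)
        D = np.array([[0.0, 12.0], [12.0, 0.0]])
        state = SimState(0, np.array([0, 3]), D, rng_state=np.ones(4))
        after = colonize(state, costd, suit.suitable_cells(), per_step_km=np.array([150.0, 150.0]))
        assert after.occupied.tolist() == [0, 1, 2, 3]
        # cell 1 colonized from 0, cell 2 from 3: the colonists carry their
        # sources' mutual divergence
        assert after.D[1, 2] == 12.0
        assert after.D[0, 1] == 0.0 and after.D[2, 3] == 0.0
        assert after.D[0, 2] == 12.0 and after.D[1, 3] == 12.0

    def test_equidistant_tie_resolves_to_lowest_source(self):
        suit, costd = self._line_costd(3)
        D = np.array([[0.0, 9.0], [9.0, 0.0]])
        state = SimState(0, np.array([0, 2]), D, rng_state=np.ones(3))
        after = colonize(state, costd, suit.suitable_cells(), per_step_km=np.array([150.0, 150.0]))
        # cell 1 equidistant from 0 and 2 -> source 0 wins
        assert after.D[0, 1] == 0.0 and after.D[1, 2] == 9.0


class TestUpdateDivergence:
    def test_isolated_pair_accumulates_three_units(self):
        state = update_divergence(pair_state(0.0), np.array([0, 1]), SimConfig())
        assert state.D[0, 1] == 3.0

    def test_connected_pair_loses_one_unit(self):
        state = update_divergence(pair_state(3.0), np.array([0, 0]), SimConfig())
        assert state.D[0, 1] == 2.0

    def test_gene_flow_floors_at_zero(self):
        state = update_divergence(pair_state(0.0), np.array([0, 0]), SimConfig())
        assert state.D[0, 1] == 0.0

    def test_commutes_with_relabeling(self):
        rng = np.random.default_rng(0)
        n = 6
        D = rng.random((n, n)) * 10
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = np.array([0, 0, 1, 1, 2, 0])
        state = SimState(0, np.arange(n), D.copy(), rng_state=np.ones(n))
        direct = update_divergence(state, labels, SimConfig()).D
        perm = rng.permutation(n)
        permuted = SimState(0, np.arange(n), D[np.ix_(perm, perm)], rng_state=np.ones(n))
        roundtrip = update_divergence(permuted, labels[perm], SimConfig()).D
        assert np.allclose(roundtrip, direct[np.ix_(perm, perm)])

    def test_closed_form_trajectory_for_random_schedules(self):
        # a isolated steps then b connected steps: D = max(0, 3a - b) * delta
        rng = np.random.default_rng(99)
        cfg = SimConfig(delta_flow=1.0, drift_multiplier=3.0)
        for _ in range(50):
            a, b = rng.integers(0, 40, size=2)
            state = pair_state(0.0)
            for _ in range(a):
                state = update_divergence(state, np.array([0, 1]), cfg)
            for _ in range(b):
                state = update_divergence(state, np.array([0, 0]), cfg)
            assert state.D[0, 1] == max(0.0, 3.0 * a - b)


class TestBurnIn:
    def test_two_isolated_refugia_accumulate_150_units(self, small_two_refugia):
        _, series = small_two_refugia
        cfg = SimConfig(seed=2, burn_in_steps=50)
        state = initialize_state(series, cfg)
        state = burn_in(state, series.steps[0], cfg)
        west = state.occupied[state.occupied % series.grid.n_cols < 3]
        east = state.occupied[state.occupied % series.grid.n_cols >= 13]
        iw = np.searchsorted(state.occupied, west)
        ie = np.searchsorted(state.occupied, east)
        assert np.all(state.D[np.ix_(iw, ie)] == 150.0)  # 50 steps x 3 units
        assert np.all(state.D[np.ix_(iw, iw)] == 0.0)

    def test_single_connected_refugium_stays_undifferentiated(self, static_series):
        cfg = SimConfig(seed=2, burn_in_steps=50, kernel=DispersalKernel(2.5, 20.0))
        state = burn_in(initialize_state(static_series, cfg), static_series.steps[0], cfg)
        assert np.all(state.D == 0.0)

    def test_zero_burn_in_is_identity(self, static_series):
        cfg = SimConfig(seed=2, burn_in_steps=0)
        state = initialize_state(static_series, cfg)
        after = burn_in(state, static_series.steps[0], cfg)
        assert np.array_equal(after.D, state.D)
        assert np.array_equal(after.occupied, state.occupied)


class TestRunSimulation:
    def test_two_refugia_form_two_clusters_then_merge(self, small_two_refugia):
        params, series = small_two_refugia
        cfg = SimConfig(seed=3, burn_in_steps=20)
        res = run_simulation(series, cfg, check_invariants=True)
        assert res.component_counts[params.glacial_steps - 1] == 2
        assert res.component_counts[-1] == 1
        # final divergence keeps the two-block refugial structure
        assert res.final_state.D.max() > 0

    def test_fully_connected_landscape_stays_at_zero(self, static_series):
        cfg = SimConfig(seed=1, burn_in_steps=5, kernel=DispersalKernel(2.5, 20.0))
        res = run_simulation(static_series, cfg)
        assert np.all(res.final_state.D == 0.0)
        assert res.component_counts == [1, 1, 1]

    def test_same_seed_is_bit_identical(self, small_two_refugia):
        _, series = small_two_refugia
        cfg = SimConfig(seed=9, burn_in_steps=10)
        r1 = run_simulation(series, cfg)
        r2 = run_simulation(series, cfg)
        assert np.array_equal(r1.final_state.D, r2.final_state.D)
        assert np.array_equal(r1.final_state.occupied, r2.final_state.occupied)

    def test_global_extinction_reports_step(self, uniform_3x3):
        suit, classes = uniform_3x3
        dead_suit, dead_classes = make_landscape(np.ones((3, 3), dtype=int))
        series = SuitabilitySeries(steps=[(suit, classes), (dead_suit, dead_classes)])
        with pytest.raises(GlobalExtinctionError, match="step 1"):
            run_simulation(series, SimConfig(seed=0, burn_in_steps=0))

    def test_within_cluster_divergence_reaches_exact_zero_and_stays(self):
        # once the two refugial lineages merge into one component, the
        # cluster's internal divergence declines to exactly 0 within
        # ceil(maxD / delta_flow) connected steps and never rebounds
        params = ScenarioParams(
            n_rows=8, n_cols=16, refugium_width=3, glacial_steps=4, postglacial_steps=40
        )
        series = two_refugia_scenario(params)
        cfg = SimConfig(seed=3, burn_in_steps=2)
        n_steps = len(series)
        res = run_simulation(series, cfg, record_D_steps=list(range(n_steps)))
        max_internal = []
        for t in range(n_steps):
            _, D = res.D_snapshots[t]
            labels = next(s for s in res.snapshots if s[0] == t)[2]
            same = labels[:, None] == labels[None, :]
            max_internal.append(float(D[same].max()))
        merge = next(
            t for t, c in enumerate(res.component_counts) if c == 1
        )
        max_at_merge = max_internal[merge]
        needed = int(np.ceil(max_at_merge / cfg.delta_flow))
        assert merge + needed < n_steps  # scenario gives the cluster time to relax
        tail = max_internal[merge:]
        assert tail == sorted(tail, reverse=True)
        assert all(v == 0.0 for v in max_internal[merge + needed :])

    def test_higher_dispersal_never_fragments_more(self):
        params = ScenarioParams(
            n_rows=8, n_cols=16, refugium_width=3, glacial_steps=8, postglacial_steps=6
        )
        series = two_refugia_scenario(params)
        counts = []
        for median in (2.0, 5.0, 20.0):
            cfg = SimConfig(seed=5, burn_in_steps=5, kernel=DispersalKernel(2.5, median))
            counts.append(run_simulation(series, cfg).component_counts[-1])
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] <= 2
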