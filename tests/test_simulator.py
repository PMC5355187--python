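"""Expansion simulator: arena stocking, frontier growth, rewiring trajectories.

Independent oracles used here:

* a breadth-first-search (BFS) distance oracle for when frontier growth
  reaches any given cell (von Neumann growth reaches a cell at its Manhattan
  distance from the release cell);
* a brute-force union-intersect recomputation of trajectories on small
  hand-specified arenas (union the contents of occupied cells at each step
  and intersect with the partner set).
"""

from collections import deque

import numpy as np
import pytest

from ecocredit import (
    Arena,
    CreditLedger,
    PartnerSet,
    PopulationState,
    build_pool,
    expand,
    ledger_from_trajectory,
    populate_arena,
    rewiring_time,
    sample_partner_set,
    simulate_rewiring,
    summarize_trajectory,
    trajectory_on_arena,
)
from ecocredit.simulator import RewiringTrajectory, replicate_seed


def bfs_steps_to_full_coverage(width, height, start):
    """Step at which von Neumann growth from `start` covers the whole grid."""
    dist = {start: 0}
    q = deque([start])
    while q:
        x, y = q.popleft()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < width and 0 <= ny < height and (nx, ny) not in dist:
                dist[(nx, ny)] = dist[(x, y)] + 1
                q.append((nx, ny))
    return max(dist.values())


def brute_force_trajectory(arena, partner_ids, release, lag_steps=0):
    """Union-intersect oracle: at each step, union occupied-cell contents and
    intersect with the partner set."""
    occupied = {release}
    seen = set()

    def richness():
        contents = set()
        for x, y in occupied:
            contents |= arena.cell_contents(x, y)
        return len(contents & set(partner_ids))

    out = [richness()] * (1 + lag_steps)
    while len(occupied) < arena.width * arena.height:
        frontier = set()
        for x, y in occupied:
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nx, ny = x + dx, y + dy
                if 0 <= nx < arena.width and 0 <= ny < arena.height:
                    frontier.add((nx, ny))
        occupied |= frontier
        out.append(richness())
    return out


class TestPopulateArena:
    def test_probability_one_occupancy_fills_every_cell(self, saturated_pool):
        arena = populate_arena(saturated_pool, 3, 3, seed=0)
        for x in range(3):
            for y in range(3):
                assert arena.cell_contents(x, y) == set(saturated_pool.species_ids)

    def test_force_seeding_places_each_rare_species_once(self):
        from ecocredit import SpeciesPool

        pool = SpeciesPool(tuple("abcd"), np.full(4, 1e-9))
        arena = populate_arena(pool, 2, 2, seed=1)
        counts = arena.presence.reshape(4, -1).sum(axis=1)
        assert np.all(counts == 1)

    def test_single_cell_arena_hosts_whole_pool(self):
        """Cells hold species sets, so even a 1x1 arena force-seeds the whole
        pool into its only cell."""
        pool = build_pool(5, "uniform", p=0.5, seed=0)
        arena = populate_arena(pool, 1, 1, seed=0)
        assert arena.cell_contents(0, 0) == set(pool.species_ids)

    def test_binomial_mean_cell_count(self):
        """Mean per-species cell count matches the binomial mean n_cells * w."""
        pool = build_pool(50, "uniform", p=0.3, seed=0)
        total = 0.0
        n_seeds = 200
        for seed in range(n_seeds):
            arena = populate_arena(pool, 20, 20, seed=seed)
            total += arena.presence.reshape(50, -1).sum(axis=1).mean()
        # per-arena per-species sd ~ sqrt(400 * .3 * .7) = 9.2;
        # averaged over 50 species x 200 seeds the SE is ~0.09
        assert abs(total / n_seeds - 0.3 * 400) < 1.0

    def test_deterministic_given_seed(self, small_pool):
        a = populate_arena(small_pool, 6, 5, seed=7)
        b = populate_arena(small_pool, 6, 5, seed=7)
        assert np.array_equal(a.presence, b.presence)


class TestExpand:
    def test_single_centre_cell_gains_four_neighbours(self, saturated_pool):
        arena = populate_arena(saturated_pool, 5, 5, seed=0)
        state = PopulationState.release(arena, (2, 2))
        nxt = expand(state, arena)
        assert nxt.step == 1
        assert nxt.occupied_cells == {(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)}

    def test_idempotent_once_full(self, saturated_pool):
        arena = populate_arena(saturated_pool, 3, 3, seed=0)
        state = PopulationState(np.ones((3, 3), dtype=bool), step=4)
        nxt = expand(state, arena)
        assert nxt.occupied_cells == state.occupied_cells

    def test_empty_occupied_set_rejected(self, saturated_pool):
        arena = populate_arena(saturated_pool, 3, 3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            expand(PopulationState(np.zeros((3, 3), dtype=bool)), arena)

    @pytest.mark.parametrize("width,height,release", [(7, 7, (3, 3)), (5, 9, (0, 0)), (6, 4, (5, 1))])
    def test_full_coverage_step_equals_bfs_distance(self, width, height, release, saturated_pool):
        arena = populate_arena(saturated_pool, width, height, seed=0)
        state = PopulationState.release(arena, release)
        steps = 0
        while not state.occupied.all():
            state = expand(state, arena)
            steps += 1
        assert steps == bfs_steps_to_full_coverage(width, height, release)


class TestTrajectoryOracle:
    def test_hand_specified_3x3_matches_union_intersect_oracle(self):
        contents = {
            (0, 0): {"a"},
            (1, 0): {"b", "c"},
            (2, 0): set(),
            (0, 1): {"d"},
            (1, 1): {"a"},
            (2, 1): {"e"},
            (0, 2): set(),
            (1, 2): {"c", "d"},
            (2, 2): {"f"},
        }
        arena = Arena.from_cell_contents(3, 3, contents)
        partners = PartnerSet("animal", frozenset({"a", "c", "e", "f"}))
        got = trajectory_on_arena(arena, partners, release_cell=(1, 1))
        want = brute_force_trajectory(arena, partners.partner_ids, (1, 1))
        assert list(got) == want

    def test_random_small_arenas_match_oracle(self, small_pool):
        """Stochastic arenas up to 4x4: simulator trajectory equals the
        brute-force union-intersect recomputation, every release cell."""
        for seed in range(20):
            arena = populate_arena(small_pool, 4, 4, seed=seed)
            partners = sample_partner_set(small_pool, 5, seed=seed + 100)
            for release in [(0, 0), (3, 3), (1, 2)]:
                got = trajectory_on_arena(arena, partners, release_cell=release)
                want = brute_force_trajectory(arena, partners.partner_ids, release)
                assert list(got) == want

    def test_lag_holds_population_at_release(self, small_pool):
        arena = populate_arena(small_pool, 4, 4, seed=3)
        partners = sample_partner_set(small_pool, 5, seed=4)
        lagged = trajectory_on_arena(arena, partners, release_cell=(1, 1), lag_steps=3)
        plain = trajectory_on_arena(arena, partners, release_cell=(1, 1))
        assert list(lagged[:4]) == [plain[0]] * 4
        assert list(lagged[4:]) == list(plain[1:])


class TestSimulateRewiring:
    def test_1x1_arena_cashes_everything_at_release(self):
        pool = build_pool(6, "uniform", p=0.4, seed=0)
        partners = sample_partner_set(pool, 4, seed=1)
        traj = simulate_rewiring(pool, partners, 1, 1, n_replicates=3, seed=2)
        assert np.all(traj.cumulative_richness == 4)
        times = rewiring_time(traj)
        assert times.times == (0, 0, 0)

    def test_endpoint_equals_degree_every_replicate(self, small_pool):
        partners = sample_partner_set(small_pool, 7, seed=0)
        traj = simulate_rewiring(small_pool, partners, 6, 6, n_replicates=20, seed=1)
        assert np.all(traj.final_richness == 7)

    def test_monotone_non_decreasing_every_replicate(self, small_pool):
        partners = sample_partner_set(small_pool, 6, seed=0)
        traj = simulate_rewiring(small_pool, partners, 8, 8, n_replicates=30, seed=5)
        assert np.all(np.diff(traj.cumulative_richness, axis=1) >= 0)

    def test_deterministic_given_seed(self, small_pool):
        partners = sample_partner_set(small_pool, 5, seed=0)
        a = simulate_rewiring(small_pool, partners, 6, 6, n_replicates=5, seed=42)
        b = simulate_rewiring(small_pool, partners, 6, 6, n_replicates=5, seed=42)
        assert np.array_equal(a.cumulative_richness, b.cumulative_richness)

    def test_generalist_dominates_nested_specialist_pointwise(self):
        """On identical arenas (same master seed), a generalist's cumulative
        richness is >= its nested specialist's at every step of every
        replicate — a deterministic dominance, not just in expectation."""
        pool = build_pool(200, seed=0)
        gen = sample_partner_set(pool, 40, seed=1, animal_id="generalist")
        spec = sample_partner_set(
            pool, 10, "nested_within", seed=2, superset=gen, animal_id="specialist"
        )
        tg = simulate_rewiring(pool, gen, 15, 15, n_replicates=25, seed=77)
        ts = simulate_rewiring(pool, spec, 15, 15, n_replicates=25, seed=77)
        assert np.all(tg.cumulative_richness >= ts.cumulative_richness)

    def test_replicates_reproducible_independently(self, small_pool):
        """Counter-based replicate seeds: replicate r alone equals row r of
        the batch run."""
        partners = sample_partner_set(small_pool, 5, seed=0)
        batch = simulate_rewiring(small_pool, partners, 5, 5, n_replicates=4, seed=9)
        arena_2 = populate_arena(small_pool, 5, 5, replicate_seed(9, 2))
        solo = trajectory_on_arena(arena_2, partners, release_cell="center")
        assert list(solo) == list(batch.cumulative_richness[2])

    def test_release_cell_outside_arena_rejected(self, small_pool):
        partners = sample_partner_set(small_pool, 3, seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_rewiring(
                small_pool, partners, 4, 4, release_cell=(4, 0), n_replicates=1, seed=0
            )

    def test_late_increments_taper_once_frontier_saturates(self):
        """Mean accumulation is asymptotic: increments over the final quartile
        of steps do not exceed the peak increment."""
        pool = build_pool(400, seed=0)
        partners = sample_partner_set(pool, 60, seed=1)
        traj = simulate_rewiring(pool, partners, 30, 30, n_replicates=20, seed=2)
        mean = traj.cumulative_richness.mean(axis=0)
        inc = np.diff(mean)
        last_quartile = inc[3 * len(inc) // 4 :]
        assert np.all(last_quartile <= inc.max())
        assert inc.max() > 0


class TestSummary:
    def test_single_replicate_collapses_band(self, small_pool):
        partners = sample_partner_set(small_pool, 4, seed=0)
        traj = simulate_rewiring(small_pool, partners, 5, 5, n_replicates=1, seed=3)
        df = summarize_trajectory(traj)
        assert (df["mean"] == df["min"]).all()
        assert (df["mean"] == df["max"]).all()

    def test_band_equals_direct_scan_of_replicate_matrix(self, small_pool):
        partners = sample_partner_set(small_pool, 6, seed=0)
        traj = simulate_rewiring(small_pool, partners, 7, 7, n_replicates=50, seed=4)
        df = summarize_trajectory(traj)
        rich = traj.cumulative_richness
        for j in range(rich.shape[1]):
            col = sorted(rich[:, j])
            assert df["min"][j] == col[0]
            assert df["max"][j] == col[-1]

    def test_identical_replicates_zero_width_band(self, small_pool):
        partners = sample_partner_set(small_pool, 4, seed=0)
        arena = populate_arena(small_pool, 5, 5, seed=8)
        row = trajectory_on_arena(arena, partners)
        traj = RewiringTrajectory(
            steps=np.arange(len(row)),
            cumulative_richness=np.vstack([row, row, row]),
            degree=partners.degree,
        )
        df = summarize_trajectory(traj)
        assert (df["max"] - df["min"] == 0).all()


class TestLedger:
    def test_arithmetic_complement(self):
        traj = RewiringTrajectory(
            steps=np.arange(3), cumulative_richness=[[0, 10, 25]], degree=25
        )
        ledger = ledger_from_trajectory(traj, credit0=25, replicate=0)
        assert list(ledger.remaining) == [25.0, 15.0, 0.0]
        assert rewiring_time(ledger) == 2

    def test_zero_credit_all_zero(self):
        traj = RewiringTrajectory(
            steps=np.arange(3), cumulative_richness=[[0, 0, 0]], degree=5
        )
        ledger = ledger_from_trajectory(traj, credit0=0, replicate=0)
        assert list(ledger.remaining) == [0.0, 0.0, 0.0]

    def test_conservation_at_every_step(self, small_pool):
        partners = sample_partner_set(small_pool, 6, seed=0)
        traj = simulate_rewiring(small_pool, partners, 6, 6, n_replicates=10, seed=1)
        for r in range(10):
            ledger = ledger_from_trajectory(traj, credit0=6, replicate=r)
            assert np.allclose(ledger.cashed + ledger.remaining, 6)
            assert np.all(np.diff(ledger.remaining) <= 0)

    def test_inconsistent_credit_rejected(self):
        traj = RewiringTrajectory(
            steps=np.arange(2), cumulative_richness=[[0, 10]], degree=10
        )
        with pytest.raises(ValueError, match="credit0"):
            ledger_from_trajectory(traj, credit0=5)

    def test_full_cashing_leaves_zero_remaining(self, small_pool):
        partners = sample_partner_set(small_pool, 8, seed=0)
        traj = simulate_rewiring(small_pool, partners, 6, 6, n_replicates=5, seed=2)
        ledger = ledger_from_trajectory(traj, credit0=8, replicate=0)
        assert ledger.remaining[-1] == 0.0


class TestRewiringTime:
    def test_first_zero_of_remaining(self):
        ledger = CreditLedger(credit0=25.0, cashed=np.array([0.0, 10.0, 25.0]))
        assert rewiring_time(ledger) == 2

    def test_not_reached_sentinel(self):
        traj = RewiringTrajectory(
            steps=np.arange(3), cumulative_richness=[[0, 1, 2]], degree=5
        )
        times = rewiring_time(traj)  # credit defaults to degree 5, never hit
        assert times.times == (None,)
        assert times.n_not_reached == 1
        assert times.median is None

    def test_probability_one_pool_matches_bfs_oracle(self):
        """All weights 1 and degree = pool size: the credit is cashed exactly
        when the frontier covers the arena, i.e. at the BFS distance."""
        pool = build_pool(9, "uniform", p=1.0, seed=0)
        partners = sample_partner_set(pool, 9, seed=1)
        for width, height in [(5, 5), (4, 7), (6, 3)]:
            traj = simulate_rewiring(
                pool, partners, width, height, n_replicates=2, seed=2
            )
            # every species is in the release cell already
            assert rewiring_time(traj).times == (0, 0)
            release = (width // 2, height // 2)
            assert traj.steps[-1] == bfs_steps_to_full_coverage(width, height, release)
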