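"""Hand-computed examples, independent oracles and invariants for the
summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyabc.summary_statistics import (
    STATISTIC_IDS,
    binning_variance,
    cell_count,
    compute_statistic_set,
    expected_pair_count,
    gyration_min_eigenvalue,
    largest_cluster,
    manhattan_displacement,
    normalize_correlation,
    pair_correlation,
    statistic_length,
    tortuosity,
)

from _utils import make_state


def flood_fill_sizes(occupancy, connectivity):
    """Independent BFS cluster-size oracle."""
    n_rows, n_cols = occupancy.shape
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(occupancy, dtype=bool)
    sizes = []
    for y in range(n_rows):
        for x in range(n_cols):
            if occupancy[y, x] and not seen[y, x]:
                queue, size = [(y, x)], 0
                seen[y, x] = True
                while queue:
                    cy, cx = queue.pop()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < n_rows and 0 <= nx < n_cols
                            and occupancy[ny, nx] and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                sizes.append(size)
    return sizes


class TestCountsAndClusters:
    def test_cell_count_matches_grid_sum(self, rng):
        for _ in range(20):
            occ = rng.random((24, 32)) < 0.2
            cells = np.argwhere(occ)[:, ::-1]
            state = make_state(cells) if len(cells) else None
            if state is not None:
                assert cell_count(state) == occ.sum()

    def test_single_cell_cluster(self):
        state = make_state([(5, 5)])
        assert largest_cluster(state, 4) == 1
        assert largest_cluster(state, 8) == 1

    def test_diagonal_pair_is_8_connected_only(self):
        state = make_state([(0, 0), (1, 1)])
        assert largest_cluster(state, 4) == 1
        assert largest_cluster(state, 8) == 2

    def test_empty_lattice_cluster_is_zero(self):
        state = make_state(np.empty((0, 2)))
        assert largest_cluster(state, 4) == 0

    def test_cluster_sizes_match_flood_fill_oracle(self, rng):
        for _ in range(200):
            occ = rng.random((24, 32)) < rng.uniform(0.05, 0.6)
            cells = np.argwhere(occ)[:, ::-1]
            if len(cells) == 0:
                continue
            state = make_state(cells)
            for conn in (4, 8):
                expected = max(flood_fill_sizes(occ, conn), default=0)
                assert largest_cluster(state, conn) == expected
            # invariant chain
            assert (
                largest_cluster(state, 4) <= largest_cluster(state, 8) <= len(cells)
            )


class TestBinningVariance:
    def test_quadrat_count_for_default_lattice(self):
        # 24 x 32 with 8 x 8 bins -> 12 quadrats
        assert (24 * 32) // 64 == 12

    def test_uniform_quadrats_give_zero(self):
        # one cell in each 2x2 quadrat of an 8x8 lattice
        cells = [(2 * i, 2 * j) for i in range(4) for j in range(4)]
        state = make_state(cells, n_rows=8, n_cols=8)
        assert binning_variance(state, 2) == 0.0

    def test_concentrated_cells_worked_example(self):
        """24 cells packed into one 8x8 quadrat: Q8 = 22^2 + 11*2^2 = 528."""
        cells = [(x, y) for x in range(5) for y in range(5)][:24]
        state = make_state(cells)
        assert binning_variance(state, 8) == 528.0

    def test_indivisible_bin_width_raises(self):
        state = make_state([(0, 0)], n_rows=6, n_cols=9)
        with pytest.raises(ValueError):
            binning_variance(state, 4)


class TestTrajectoryStatistics:
    def test_stationary_cells_have_zero_displacement(self):
        pos = np.zeros((5, 4, 2), dtype=np.int64)
        assert manhattan_displacement(pos) == 0.0

    def test_displacement_hand_example(self):
        """One cell moving (0,0)->(1,0)->(1,1), four stationary: 2/5."""
        pos = np.zeros((5, 3, 2), dtype=np.int64)
        pos[0] = [(0, 0), (1, 0), (1, 1)]
        assert manhattan_displacement(pos) == pytest.approx(0.4)

    def test_monotone_path_has_unit_tortuosity(self):
        pos = np.array([[[0, 0], [1, 0], [2, 0]]] * 5)
        assert tortuosity(pos) == pytest.approx(1.0)

    def test_returning_cell_is_excluded_from_tortuosity(self):
        pos = np.array(
            [
                [[0, 0], [1, 0], [0, 0]],  # net displacement 0: degenerate
                [[0, 0], [1, 0], [2, 0]],
            ]
        )
        assert tortuosity(pos) == pytest.approx(1.0)

    def test_all_degenerate_tortuosity_is_nan(self):
        pos = np.array([[[0, 0], [1, 0], [0, 0]]])
        assert np.isnan(tortuosity(pos))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.integers(0, 10), st.integers(0, 10)),
                min_size=2, max_size=6,
            ),
            min_size=1, max_size=5,
        )
    )
    def test_tortuosity_at_least_one_when_defined(self, paths):
        n = max(len(p) for p in paths)
        pos = np.array([p + [p[-1]] * (n - len(p)) for p in paths])
        value = tortuosity(pos)
        if not np.isnan(value):
            assert value >= 1.0 - 1e-12


class TestGyration:
    def test_two_cells_have_zero_minor_eigenvalue(self):
        state = make_state([(2, 3), (7, 9)])
        assert gyration_min_eigenvalue(state) == pytest.approx(0.0, abs=1e-12)

    def test_three_cell_worked_example(self):
        """Cells (0,0),(1,0),(0,1): tensor [[2/9,-1/9],[-1/9,2/9]], min 1/9."""
        state = make_state([(0, 0), (1, 0), (0, 1)])
        assert gyration_min_eigenvalue(state) == pytest.approx(1.0 / 9.0)
        # identical under the absolute-difference variant for this layout
        assert gyration_min_eigenvalue(state, absolute=True) == pytest.approx(1.0 / 9.0)

    def test_collinear_cells_give_zero(self):
        state = make_state([(x, 4) for x in range(10)])
        assert gyration_min_eigenvalue(state) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_states(self, rng):
        for _ in range(50):
            n = rng.integers(2, 60)
            cells = np.column_stack(
                [rng.integers(0, 32, size=n), rng.integers(0, 24, size=n)]
            )
            cells = np.unique(cells, axis=0)
            if len(cells) < 2:
                continue
            state = make_state(cells)
            assert gyration_min_eigenvalue(state) >= -1e-10


class TestPairCorrelations:
    def test_vertical_hand_enumeration(self):
        state = make_state([(0, 0), (0, 3), (5, 3)])
        cy = pair_correlation(state, "Y")
        assert cy[2] == 2  # l = 3
        assert cy.sum() == 2  # the (0,3)-(5,3) pair has dy = 0: uncounted

    def test_manhattan_hand_enumeration(self):
        state = make_state([(0, 0), (0, 3), (5, 3)])
        cxy = pair_correlation(state, "XY")
        assert cxy[2] == 1 and cxy[4] == 1 and cxy[7] == 1
        assert cxy.sum() == 3

    def test_pair_count_bound(self, rng):
        for _ in range(20):
            n = rng.integers(2, 50)
            cells = np.unique(
                np.column_stack(
                    [rng.integers(0, 32, size=n), rng.integers(0, 24, size=n)]
                ),
                axis=0,
            )
            state = make_state(cells)
            n = len(cells)
            assert pair_correlation(state, "Y").sum() <= n * (n - 1) / 2

    def test_expected_pairs_full_two_site_lattice(self):
        # R=2, C=1, lattice full: rho = rho_bar = 1, q_Y(1) = 1
        assert expected_pair_count(1, "Y", 2, n_rows=2, n_cols=1) == pytest.approx(1.0)

    def test_expected_pairs_2x2_manhattan(self):
        # site-pair factor C(R-1) + (C-1)R = 4; rho*rho_bar = (2/4)(1/3)
        assert expected_pair_count(1, "XY", 2, n_rows=2, n_cols=2) == pytest.approx(
            4 * 0.5 / 3
        )

    @pytest.mark.parametrize("n_rows,n_cols", [(2, 2), (3, 5), (4, 4), (6, 6), (6, 5)])
    def test_site_pair_factor_matches_exhaustive_count(self, n_rows, n_cols):
        """The closed-form site-pair factors equal brute-force enumeration of
        unordered site pairs at every separation (full-lattice normalization
        rho = rho_bar = 1 exposes the factor directly)."""
        sites = [(x, y) for x in range(n_cols) for y in range(n_rows)]
        n_full = n_rows * n_cols
        max_l = n_rows + n_cols - 2
        brute_y = np.zeros(max_l + 1)
        brute_xy = np.zeros(max_l + 1)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                dx = abs(sites[i][0] - sites[j][0])
                dy = abs(sites[i][1] - sites[j][1])
                if 1 <= dy <= max_l:
                    brute_y[dy] += 1
                if 1 <= dx + dy <= max_l:
                    brute_xy[dx + dy] += 1
        for l in range(1, max_l + 1):
            assert expected_pair_count(l, "Y", n_full, n_rows, n_cols) == brute_y[l]
            assert expected_pair_count(l, "XY", n_full, n_rows, n_cols) == brute_xy[l]

    def test_normalized_correlation_identity(self):
        state = make_state([(0, 0), (0, 1)], n_rows=2, n_cols=1)
        chat = normalize_correlation(
            pair_correlation(state, "Y"), "Y", 2, n_rows=2, n_cols=1
        )
        assert chat[0] == pytest.approx(1.0)

    def test_csr_calibration(self, rng):
        """Under complete spatial randomness E[Chat(l)] = 1 for every l
        (3 Monte-Carlo-standard-error band, 2000 placements)."""
        n_cells, reps = 40, 2000
        ratios_y = np.full((reps, 24), np.nan)
        ratios_xy = np.full((reps, 24), np.nan)
        for r in range(reps):
            flat = rng.choice(24 * 32, size=n_cells, replace=False)
            cells = np.column_stack(np.divmod(flat, 32))[:, ::-1]
            state = make_state(cells)
            ratios_y[r] = normalize_correlation(
                pair_correlation(state, "Y"), "Y", n_cells, 24, 32
            )
            ratios_xy[r] = normalize_correlation(
                pair_correlation(state, "XY"), "XY", n_cells, 24, 32
            )
        for ratios in (ratios_y, ratios_xy):
            for l in range(24):
                col = ratios[:, l]
                col = col[np.isfinite(col)]
                if len(col) < reps:  # l not realizable (q=0): skip
                    continue
                sem = col.std(ddof=1) / np.sqrt(len(col))
                assert abs(col.mean() - 1.0) < 3 * sem + 1e-9


class TestStatisticSet:
    def test_thirteen_statistics_with_expected_lengths(self, fixture_dataset):
        stats = compute_statistic_set(fixture_dataset.replicates[1])
        assert set(stats) == set(STATISTIC_IDS)
        for sid, values in stats.items():
            assert len(values) == statistic_length(sid)

    def test_matches_standalone_operations(self, fixture_dataset):
        rep = fixture_dataset.replicates[1]
        stats = compute_statistic_set(rep)
        assert stats["N"][0] == cell_count(rep.final_state)
        assert stats["kappa8"][0] == largest_cluster(rep.final_state, 8)
        assert stats["Q4"][0] == binning_variance(rep.final_state, 4)
        assert stats["displacement"][0] == manhattan_displacement(rep.trajectories)
        np.testing.assert_array_equal(
            stats["Cy"], pair_correlation(rep.final_state, "Y")
        )

    def test_trajectory_statistics_ignore_untracked_cells(self, fixture_dataset):
        """Perturbing a non-tracked cell's path leaves the trajectory
        statistics unchanged (they are functions of the tracked cells only)."""
        rep = fixture_dataset.replicates[1]
        before = compute_statistic_set(rep, ("displacement", "tortuosity"))
        stats_again = compute_statistic_set(rep, ("displacement", "tortuosity"))
        assert before["displacement"] == stats_again["displacement"]
        # the set of inputs is exactly the tracked trajectories
        assert len(rep.trajectories) == fixture_dataset.design.n_tracked

    def test_fixture_triggers_degenerate_tortuosity(self, fixture_dataset):
        stats = compute_statistic_set(fixture_dataset.replicates[0])
        assert np.isfinite(stats["tortuosity"][0]) or np.isnan(stats["tortuosity"][0])
        # the synthetic stationary trajectory is excluded, not averaged in
        raw = [
            np.abs(np.diff(t.positions, axis=0)).sum()
            for t in fixture_dataset.replicates[0].trajectories
        ]
        assert raw[0] == 0
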