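"""NODF family of metrics and the pool-resampling comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import montinv as mv
from montinv.core import ElevationalBands, IncidenceMatrix, SpeciesRecord
from montinv.nestedness import _best_staircase, _exhaustive_max

from conftest import nodf_oracle


def _sp(name, lo, hi, status="alien"):
    return SpeciesRecord(name=name, status=status,
                         alien_class="naturalised" if status == "alien" else "none",
                         regions=frozenset({"JK"}), elev_min=lo, elev_max=hi)


class TestNodf:
    def test_perfectly_nested_triangle_is_100(self):
        A = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert mv.nodf(A).nodf_total == pytest.approx(100.0)

    def test_hand_example_rows_equal_fill(self):
        # rows {110, 011}: row pair ties (0); columns score 100, 100, 0
        res = mv.nodf(np.array([[1, 1, 0], [0, 1, 1]]))
        assert res.nodf_total == pytest.approx(50.0)
        assert res.nodf_rows == pytest.approx(0.0)
        assert res.nodf_cols == pytest.approx(200.0 / 3.0)

    def test_checkerboard_is_zero(self):
        assert mv.nodf(np.array([[1, 0], [0, 1]])).nodf_total == 0.0

    def test_degenerate_matrices_raise(self):
        with pytest.raises(ValueError):
            mv.nodf(np.array([[1, 1]]))
        with pytest.raises(ValueError, match="empty"):
            mv.nodf(np.array([[1, 0], [1, 0]]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        A = (rng.random((6, 5)) < 0.5).astype(int)
        A = A[A.sum(1) > 0][:, A.sum(0) > 0]
        base = mv.nodf(A).nodf_total
        for _ in range(5):
            P = A[rng.permutation(A.shape[0])][:, rng.permutation(A.shape[1])]
            assert mv.nodf(P).nodf_total == pytest.approx(base)

    @given(arrays(np.int8, (4, 4), elements=st.integers(0, 1)))
    def test_matches_pairwise_oracle(self, A):
        if (A.sum(1) == 0).any() or (A.sum(0) == 0).any():
            return
        assert mv.nodf(A).nodf_total == pytest.approx(nodf_oracle(A))


class TestMaxNodf:
    def test_2x2_fill3_enumeration(self):
        # {11, 10}: row pair 100, column pair 100
        assert mv.max_nodf(2, 2, 3) == pytest.approx(100.0)

    def test_full_matrix_has_no_decreasing_fill(self):
        assert mv.max_nodf(3, 3, 9) == 0.0

    def test_infeasible_fill_raises(self):
        with pytest.raises(ValueError):
            mv.max_nodf(3, 3, 2)
        with pytest.raises(ValueError):
            mv.max_nodf(3, 3, 10)

    @pytest.mark.parametrize("r,c,fill", [(3, 3, 6), (3, 3, 7), (4, 4, 8),
                                          (4, 4, 11), (2, 8, 9), (4, 3, 7)])
    def test_heuristic_equals_exhaustive_small(self, r, c, fill):
        exact = mv.max_nodf(r, c, fill)  # exhaustive (<=16 cells)
        heur = mv.max_nodf(r, c, fill, exhaustive_limit=0,
                           refine_steps=400, restarts=3)
        assert heur == pytest.approx(exact)

    def test_upper_bounds_random_observed_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r, c = rng.integers(3, 8, size=2)
            A = np.zeros((r, c), dtype=int)
            while (A.sum(1) == 0).any() or (A.sum(0) == 0).any():
                A = (rng.random((r, c)) < rng.uniform(0.3, 0.8)).astype(int)
            mx = mv.max_nodf(r, c, int(A.sum()), exhaustive_limit=16,
                             refine_steps=400, restarts=3)
            assert mx + 1e-9 >= mv.nodf(A).nodf_total


class TestNodfc:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        A = np.array([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0]])
        base = mv.nodfc(A).nodf_c
        P = A[rng.permutation(4)][:, rng.permutation(4)]
        assert mv.nodfc(P).nodf_c == pytest.approx(base)

    def test_component_chain(self):
        """NODFc composes NODF, NODFmax, connectance and ln(S) exactly."""
        A = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        res = mv.nodfc(A)
        C = 6 / 9
        S = 3.0
        assert res.nodf_max == pytest.approx(100.0)
        assert res.nodf_c == pytest.approx(
            (res.nodf_total / res.nodf_max) / (C * np.log(S)))

    def test_all_ones_matrix_raises(self):
        with pytest.raises(ValueError, match="NODFmax = 0"):
            mv.nodfc(np.ones((3, 3), dtype=int))


class TestTreeNodf:
    def test_star_tree_reduces_to_column_nodf(self):
        """With no internal structure and equal pendant branches, shared
        branch length is proportional to shared species, so treeNODF equals
        the species-level column NODF and the T-fraction vanishes."""
        star = mv.read_newick("(a:1,b:1,c:1,d:1);")
        A = np.array([[1, 1, 0], [1, 1, 0], [1, 0, 1], [1, 0, 0]])
        m = IncidenceMatrix(["a", "b", "c", "d"], ["s1", "s2", "s3"], A)
        t = mv.tree_nodf(m, star)
        assert t.total == pytest.approx(mv.nodf(A).nodf_cols)
        assert t.t_fraction == pytest.approx(0.0)
        assert t.s_fraction + t.t_fraction == pytest.approx(t.total)

    def test_subset_community_scores_100(self):
        tree = mv.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = IncidenceMatrix(["a", "b", "c", "d"], ["big", "small"],
                            np.array([[1, 1], [1, 0], [1, 0], [0, 0]]))
        assert mv.tree_nodf(m, tree).total == pytest.approx(100.0)

    def test_disjoint_clades_score_zero(self):
        tree = mv.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = IncidenceMatrix(["a", "b", "c", "d"], ["i", "j"],
                            np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        assert mv.tree_nodf(m, tree).total == 0.0

    def test_shared_internal_branch_yields_t_fraction(self):
        # i holds {a, c}, j holds {b}: no shared species, but a and b share
        # their stem edge, so the whole overlap is topological
        tree = mv.read_newick("((a:1,b:1):2,c:3);")
        m = IncidenceMatrix(["a", "b", "c"], ["i", "j"],
                            np.array([[1, 0], [0, 1], [1, 0]]))
        t = mv.tree_nodf(m, tree)
        # BL(i) = 1 + 2 + 3 = 6 > BL(j) = 1 + 2 = 3; shared = stem only (2)
        assert t.total == pytest.approx(100 * 2 / 3)
        assert t.s_fraction == 0.0
        assert t.t_fraction == pytest.approx(t.total)

    def test_missing_species_raises(self, toy_tree):
        m = IncidenceMatrix(["a", "zz"], ["i", "j"], np.array([[1, 1], [1, 0]]))
        with pytest.raises(ValueError, match="missing"):
            mv.tree_nodf(m, toy_tree)


class TestElevationalNestedness:
    def test_identical_full_gradient_ranges_score_zero(self):
        recs = [_sp(f"S_{i}", 0, 5000) for i in range(5)]
        res = mv.elevational_nestedness(recs, group="alien", refine_steps=0)
        assert res.nodf_total == 0.0
        assert res.nodf_c is None  # completely filled: NODFc undefined

    def test_hand_small_case(self):
        """One shared bottom band, disjoint tops: only the pairs against the
        full-range species can nest."""
        bands = ElevationalBands(width=1000, floor=0, ceiling=3000)
        recs = [
            _sp("Full_sp", 0, 3000),     # occupies all 3 bands
            _sp("Low_sp", 0, 900),       # band 1
            _sp("High_sp", 2100, 2900),  # band 3
        ]
        res = mv.elevational_nestedness(recs, bands=bands, group="alien")
        # rows: Full(3) vs Low(1): overlap 1 -> 100; Full vs High: 100;
        # Low vs High equal fill -> 0.  cols: fills (2,1,2): col1 vs col2
        # 100, col3 vs col2 100, col1/col3 tie -> 0
        assert res.nodf_total == pytest.approx((100 + 100 + 100 + 100) / 6)

    def test_directional_filtering_beats_random_natives(self):
        """Anchored aliens with exponential upward spread are reliably more
        nested (NODFc) than equal-sized random-midpoint native floras."""
        wins = 0
        for seed in range(10):
            cfg = mv.SimulationConfig(n_native=300, n_alien=300, seed=seed)
            recs = mv.simulate_pool(cfg)
            a = mv.elevational_nestedness(recs, group="alien", refine_steps=0)
            n = mv.elevational_nestedness(recs, group="native", refine_steps=0)
            wins += a.nodf_c > n.nodf_c
        assert wins >= 9

    def test_regions_sites_low_elevation_restriction(self, pool):
        res = mv.elevational_nestedness(pool, group="alien", sites="regions")
        assert res.n_cols <= 6
        assert res.nodf_c is not None and res.nodf_c >= 0

    def test_too_few_occupied_bands_raise(self):
        recs = [_sp("A_a", 0, 100), _sp("B_b", 50, 150)]
        with pytest.raises(ValueError, match="occupied"):
            mv.elevational_nestedness(recs, group="alien")


class TestComparePools:
    def test_seeded_runs_are_identical(self, pool):
        jk = [r for r in pool if r.in_region("JK")]
        a = mv.compare_pools(jk, draws=5, seed=123)
        b = mv.compare_pools(jk, draws=5, seed=123)
        for band in a.native_draws:
            assert np.array_equal(a.native_draws[band], b.native_draws[band],
                                  equal_nan=True)
        assert a.overall_delta == b.overall_delta

    def test_identical_pools_give_small_delta(self):
        """When 'aliens' are relabelled natives the two sampling
        distributions coincide and the mean difference stays tiny."""
        rng = np.random.default_rng(5)
        n = 300
        mid = rng.uniform(0, 5000, n)
        half = rng.exponential(600, n)
        lo, hi = np.maximum(0, mid - half), np.minimum(5000, mid + half)
        recs = [_sp(f"S_{i}", lo[i], hi[i],
                    status="alien" if i % 2 else "native") for i in range(n)]
        res = mv.compare_pools(recs, draws=30, seed=9)
        assert abs(res.overall_delta) < 0.05

    def test_draw_counts_match_configuration(self, pool):
        jk = [r for r in pool if r.in_region("JK")]
        res = mv.compare_pools(jk, draws=4, seed=1)
        assert res.draws == 4
        for band, vals in res.alien_draws.items():
            assert len(vals) == 4
        assert (res.per_band["delta"]
                == res.per_band["mean_alien"] - res.per_band["mean_native"]).all()

    def test_empty_pool_raises(self):
        recs = [_sp(f"S_{i}", 0, 1000, status="native") for i in range(10)]
        with pytest.raises(ValueError, match="pool"):
            mv.compare_pools(recs)
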