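"""Grafting, MPD/MNTD, NRI/NTI and rarefied species:genus ratios."""

import dendropy
import numpy as np
import pytest

import montinv as mv
from montinv.core import SpeciesRecord


def _rec(name, family):
    return SpeciesRecord(name=name, family=family)


class TestGrafting:
    def test_half_distance_rule_worked_example(self):
        """Family node at depth 5, exemplar tip 10 below it: the grafted
        congener creates a genus node at depth 10 with both tips hanging 5
        below it, so their patristic distance is 10."""
        bb = mv.read_newick(
            "((Alpha_one:10,Beta_one:10):5,Gamma_one:15);",
            genus_to_family={"Alpha": "Fam1", "Beta": "Fam1", "Gamma": "Fam2"},
        )
        g = mv.graft_tips(bb, [_rec("Alpha_two", "Fam1")])
        labels, D = g.distance_matrix()
        i = {l: k for k, l in enumerate(labels)}
        assert D[i["Alpha_one"], i["Alpha_two"]] == pytest.approx(10.0)
        # genus node midway: both tips 5 from it, and the new tip is
        # contemporaneous with everything else
        assert g.tip_depths()["Alpha_two"] == pytest.approx(15.0)
        # existing distances untouched
        assert D[i["Alpha_one"], i["Beta_one"]] == pytest.approx(20.0)
        assert D[i["Alpha_one"], i["Gamma_one"]] == pytest.approx(30.0)

    def test_new_genus_joins_family_basal_node(self):
        bb = mv.read_newick(
            "((Alpha_one:10,Beta_one:10):5,Gamma_one:15);",
            genus_to_family={"Alpha": "Fam1", "Beta": "Fam1", "Gamma": "Fam2"},
        )
        g = mv.graft_tips(bb, [_rec("Delta_one", "Fam1")])
        labels, D = g.distance_matrix()
        i = {l: k for k, l in enumerate(labels)}
        # attached at the Fam1 crown (depth 5): 10 down to each tip
        assert D[i["Delta_one"], i["Alpha_one"]] == pytest.approx(20.0)
        assert D[i["Delta_one"], i["Beta_one"]] == pytest.approx(20.0)

    def test_existing_genus_crown_graft(self):
        bb = mv.read_newick(
            "(((Alpha_one:4,Alpha_two:4):6,Beta_one:10):5,Gamma_one:15);",
            genus_to_family={"Alpha": "Fam1", "Beta": "Fam1", "Gamma": "Fam2"},
        )
        g = mv.graft_tips(bb, [_rec("Alpha_three", "Fam1")])
        labels, D = g.distance_matrix()
        i = {l: k for k, l in enumerate(labels)}
        # joined at the Alpha crown node (depth 11): 4 down to each congener
        assert D[i["Alpha_three"], i["Alpha_one"]] == pytest.approx(8.0)
        assert D[i["Alpha_three"], i["Beta_one"]] == pytest.approx(20.0)

    def test_zero_grafts_identity(self, backbone):
        g = mv.graft_tips(backbone, [])
        l0, D0 = backbone.distance_matrix()
        l1, D1 = g.distance_matrix()
        order = [l1.index(l) for l in l0]
        assert np.allclose(D0, D1[np.ix_(order, order)], atol=1e-12)

    def test_unknown_family_raises(self, backbone):
        with pytest.raises(ValueError, match="absent"):
            mv.graft_tips(backbone, [_rec("Nullius_nemo", "Nowhereaceae")])

    def test_duplicate_tip_raises(self, backbone):
        first = backbone.tip_labels[0]
        fam = backbone.family_of(first)
        with pytest.raises(ValueError, match="duplicate"):
            mv.graft_tips(backbone, [_rec(first, fam)])

    def test_bulk_graft_preserves_ultrametricity_and_distances(self):
        cfg = mv.SimulationConfig(n_native=30, n_alien=10, n_genera=10,
                                  n_families=4, seed=7)
        bb = mv.simulate_backbone(cfg)
        assert bb.n_tips == 10 and bb.is_ultrametric(1e-9)
        pool = mv.simulate_pool(cfg)
        ex = set(bb.tip_labels)
        extra = [r for r in pool if r.name not in ex][:30]
        g = mv.graft_tips(bb, extra)
        assert g.n_tips == 40
        depths = list(g.tip_depths().values())
        assert max(depths) - min(depths) < 1e-9
        l0, D0 = bb.distance_matrix()
        l1, D1 = g.distance_matrix()
        order = [l1.index(l) for l in l0]
        assert np.allclose(D0, D1[np.ix_(order, order)], atol=1e-9)


class TestMpdMntd:
    def test_toy_tree_hand_sums(self, toy_tree):
        assert mv.mpd(["a", "b", "c"], toy_tree) == pytest.approx(10 / 3)
        assert mv.mntd(["a", "b", "c"], toy_tree) == pytest.approx(8 / 3)

    def test_two_tip_community_equals_patristic_distance(self, toy_tree):
        assert mv.mpd(["a", "c"], toy_tree) == mv.mntd(["a", "c"], toy_tree) == 4.0

    def test_star_tree_symmetry(self):
        star = mv.read_newick("(a:3,b:3,c:3,d:3);")
        for comm in (["a", "b"], ["a", "b", "c", "d"]):
            assert mv.mpd(comm, star) == pytest.approx(6.0)
            assert mv.mntd(comm, star) == pytest.approx(6.0)

    def test_singleton_community_raises(self, toy_tree):
        with pytest.raises(ValueError):
            mv.mpd(["a"], toy_tree)

    def test_against_dendropy_path_oracle(self):
        """MPD/MNTD agree with dendropy's own patristic distances on small
        random trees (independent implementation of path lengths)."""
        rng = np.random.default_rng(42)
        for rep in range(5):
            n = int(rng.integers(4, 13))
            cfg = mv.SimulationConfig(n_native=n, n_alien=0, n_genera=n,
                                      n_families=2, seed=100 + rep)
            tree = mv.simulate_backbone(cfg)
            pdm = tree.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.tree.taxon_namespace}
            labels = tree.tip_labels
            k = int(rng.integers(2, n + 1))
            comm = list(rng.choice(labels, size=k, replace=False))
            exp_pairs = [
                pdm.patristic_distance(taxa[a], taxa[b])
                for ai, a in enumerate(comm) for b in comm[ai + 1:]
            ]
            assert mv.mpd(comm, tree) == pytest.approx(np.mean(exp_pairs))
            exp_mntd = np.mean([
                min(pdm.patristic_distance(taxa[a], taxa[b])
                    for b in comm if b != a)
                for a in comm
            ])
            assert mv.mntd(comm, tree) == pytest.approx(exp_mntd)


class TestStandardizedIndex:
    def test_community_equal_to_pool_is_zero(self, toy_tree):
        assert mv.standardized_index(["a", "b", "c"], toy_tree,
                                     iterations=99).value == 0.0

    def test_one_clade_of_two_distant_clades_is_clustered(self):
        left = ",".join(f"L{i}:1" for i in range(6))
        right = ",".join(f"R{i}:1" for i in range(6))
        tree = mv.read_newick(f"(({left}):50,({right}):50);")
        res = mv.standardized_index([f"L{i}" for i in range(6)], tree,
                                    iterations=999, seed=5)
        assert res.value > 1.96 and res.significant

    def test_branch_length_scaling_invariance(self, backbone):
        labels = backbone.tip_labels[:10]
        a = mv.standardized_index(labels, backbone, iterations=199, seed=9)
        scaled = backbone.clone()
        for e in scaled.tree.preorder_edge_iter():
            if e.length:
                e.length *= 7.3
        b = mv.standardized_index(labels, scaled, iterations=199, seed=9)
        assert a.value == pytest.approx(b.value, abs=1e-9)

    def test_sign_convention_positive_means_clustering(self):
        """A community with tiny observed MPD relative to the null gets a
        positive index (clustering)."""
        left = ",".join(f"L{i}:1" for i in range(4))
        tree = mv.read_newick(f"(({left}):50,(R0:1,R1:1):50);")
        res = mv.standardized_index(["L0", "L1", "L2"], tree,
                                    iterations=499, seed=2)
        assert res.observed < res.null_mean
        assert res.value > 0


class TestGenusRatios:
    def _recs(self, sizes):
        out = []
        for g, k in sizes.items():
            for i in range(k):
                out.append(SpeciesRecord(name=f"{g}_sp{i}", genus=g))
        return out

    def test_full_genus_count_equals_plain_ratio(self):
        recs = self._recs({"A": 4, "B": 2, "C": 1})
        res = mv.genus_ratio_rarefied(recs, 3, draws=20, seed=0)
        assert res.ratio == pytest.approx(7 / 3)
        assert res.rarefied_mean == pytest.approx(res.ratio)
        assert res.rarefied_lo == res.rarefied_hi == pytest.approx(res.ratio)

    def test_monotypic_genera_give_ratio_one(self):
        recs = self._recs({"A": 1, "B": 1, "C": 1, "D": 1})
        res = mv.genus_ratio_rarefied(recs, 2, draws=50, seed=0)
        assert res.rarefied_mean == 1.0 and res.ratio == 1.0

    def test_exhaustive_enumeration_oracle(self):
        """Genera of 4/2/1 species rarefied to 2: the three equally likely
        pairs give ratios 3, 2.5, 1.5, mean 7/3."""
        recs = self._recs({"A": 4, "B": 2, "C": 1})
        res = mv.genus_ratio_rarefied(recs, 2, draws=3000, seed=1)
        assert res.rarefied_mean == pytest.approx(7 / 3, abs=0.05)
        assert res.rarefied_lo <= res.rarefied_mean <= res.rarefied_hi

    def test_zero_target_raises(self):
        with pytest.raises(ValueError):
            mv.genus_ratio_rarefied(self._recs({"A": 2}), 0)

    def test_band_table_shapes(self, pool):
        df = mv.band_genus_ratios(pool, draws=20, seed=0)
        assert (df["native_ratio"].dropna() >= 1).all()
        assert (df["alien_ratio"].dropna() >= 1).all()
        ok = df.dropna(subset=["native_rarefied_mean"])
        assert (ok["native_rarefied_lo"] <= ok["native_rarefied_mean"] + 1e-12).all()
        assert (ok["native_rarefied_mean"] <= ok["native_rarefied_hi"] + 1e-12).all()


def test_band_phylo_indices_frame(pool, backbone):
    ex = set(backbone.tip_labels)
    tree = mv.graft_tips(backbone, [r for r in pool if r.name not in ex])
    df = mv.band_phylo_indices(pool, tree, iterations=99, seed=3,
                               groups=("alien",))
    with_data = df.dropna(subset=["mpd"])
    assert len(with_data) > 5
    assert (with_data["mpd"] >= 0).all() and (with_data["mntd"] >= 0).all()
    assert np.isfinite(with_data["nri"]).all()
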