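import dendropy
import numpy as np
import pandas as pd
import pytest

from wingmorph.morphospace import fit_shape_space, project
from wingmorph.phylo import (
    asr_bm,
    kmult,
    phylo_vcv,
    phylomorphospace,
    read_newick,
    tip_labels,
    write_newick,
)
from wingmorph.synth import gen_tree, simulate_bm


def tree_from(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick")


class TestVCV:
    def test_two_independent_tips(self):
        C = phylo_vcv(tree_from("(A:1.0,B:1.0);"), ["A", "B"])
        assert np.allclose(C, np.eye(2))

    def test_three_tip_ultrametric(self):
        C = phylo_vcv(tree_from("((A:1,B:1):1,C:2);"), ["A", "B", "C"])
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_matches_brute_force_paths_on_random_tree(self):
        tree = gen_tree(20, seed=5)
        labels = tip_labels(tree)
        C = phylo_vcv(tree, labels)
        # oracle: dendropy's own MRCA + root distances
        pdm = {}
        tree2 = tree.clone(depth=1)
        tree2.calc_node_root_distances()
        leaves = {lf.taxon.label: lf for lf in tree2.leaf_node_iter()}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if a == b:
                    expected = leaves[a].root_distance
                else:
                    mrca = tree2.mrca(taxa=[leaves[a].taxon, leaves[b].taxon])
                    expected = mrca.root_distance or 0.0
                assert np.isclose(C[i, j], expected), (a, b)

    def test_positive_definite(self, small_tree):
        C = phylo_vcv(small_tree)
        assert np.linalg.eigvalsh(C).min() > 0


class TestNewickIO:
    def test_round_trip_preserves_topology_and_lengths(self, small_tree, tmp_path):
        p = tmp_path / "t.nwk"
        write_newick(small_tree, p)
        back = read_newick(p)
        assert sorted(tip_labels(back)) == sorted(tip_labels(small_tree))
        C1 = phylo_vcv(small_tree, sorted(tip_labels(small_tree)))
        C2 = phylo_vcv(back, sorted(tip_labels(back)))
        assert np.allclose(C1, C2, atol=1e-9)

    def test_duplicate_tips_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("(A:1,(A:1,B:1):1);")
        with pytest.raises(ValueError, match="duplicate"):
            read_newick(p)

    def test_missing_lengths_rejected(self, tmp_path):
        p = tmp_path / "nolen.nwk"
        p.write_text("(A,(B,C));")
        with pytest.raises(ValueError, match="branch length"):
            read_newick(p)


class TestASR:
    def test_two_tip_symmetric_root(self):
        t = tree_from("(A:1.0,B:1.0);")
        traits = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        assert np.isclose(asr_bm(t, traits).iloc[0, 0], 1.0)

    def test_two_tip_inverse_length_weighting(self):
        # branches (1, 3), tips (0, 4): root = (0/1 + 4/3)/(1 + 1/3) = 1
        t = tree_from("(A:1.0,B:3.0);")
        traits = pd.DataFrame({"x": [0.0, 4.0]}, index=["A", "B"])
        assert np.isclose(asr_bm(t, traits).iloc[0, 0], 1.0)

    def test_constant_trait_everywhere(self, small_tree):
        labels = tip_labels(small_tree)
        traits = pd.DataFrame({"x": np.full(len(labels), 3.7)}, index=labels)
        est = asr_bm(small_tree, traits)
        assert np.allclose(est.to_numpy(), 3.7)

    def test_multivariate_equals_per_trait(self, small_tree):
        labels = tip_labels(small_tree)
        rng = np.random.default_rng(0)
        traits = pd.DataFrame(
            rng.normal(size=(len(labels), 3)), index=labels, columns=list("abc")
        )
        joint = asr_bm(small_tree, traits)
        for col in "abc":
            single = asr_bm(small_tree, traits[[col]])
            assert np.allclose(joint[col], single[col], atol=1e-10)

    def test_unmatched_tips_rejected(self, small_tree):
        traits = pd.DataFrame({"x": [1.0, 2.0]}, index=["t0", "t1"])
        with pytest.raises(ValueError, match="without trait"):
            asr_bm(small_tree, traits)


class TestPhylomorphospace:
    def _setup(self, tree, coefficient_matrix):
        labels = tip_labels(tree)
        X = coefficient_matrix[: len(labels)]
        traits = pd.DataFrame(X, index=labels)
        space = fit_shape_space(coefficient_matrix)
        return traits, space

    def test_edge_count_matches_branches(self, small_tree, coefficient_matrix):
        traits, space = self._setup(small_tree, coefficient_matrix)
        pms = phylomorphospace(small_tree, traits, space)
        n_tips = len(tip_labels(small_tree))
        connected = pms[pms["parent_id"] != ""]
        # every non-root node contributes its parent edge
        assert len(connected) == 2 * n_tips - 2

    def test_projection_commutes_with_asr(self, small_tree, coefficient_matrix):
        # projecting reconstructed coefficients = reconstructing projected
        # scores (both maps are linear)
        traits, space = self._setup(small_tree, coefficient_matrix)
        anc_coeff = asr_bm(small_tree, traits)
        direct = project(anc_coeff.to_numpy(), space)
        score_traits = pd.DataFrame(
            project(traits.to_numpy(), space), index=traits.index
        )
        via_scores = asr_bm(small_tree, score_traits).to_numpy()
        assert np.allclose(direct, via_scores, atol=1e-8)

    def test_star_tree_symmetric_tips_root_at_origin(
        self, star_tree, coefficient_matrix
    ):
        labels = tip_labels(star_tree)
        X = coefficient_matrix[: len(labels)]
        traits = pd.DataFrame(X, index=labels)
        space = fit_shape_space(X)  # mean of these tips = space origin
        pms = phylomorphospace(star_tree, traits, space)
        root = pms[pms["type"] == "internal"].iloc[0]
        assert abs(root["pc1"]) < 1e-8 and abs(root["pc2"]) < 1e-8

    def test_unplaced_taxa_included(self, small_tree, coefficient_matrix):
        traits, space = self._setup(small_tree, coefficient_matrix)
        extra = pd.DataFrame(
            {"pc1": [0.1], "pc2": [0.2]}, index=["loner"]
        )
        pms = phylomorphospace(small_tree, traits, space, extra_scores=extra)
        row = pms[pms["node_id"] == "loner"].iloc[0]
        assert row["type"] == "unplaced" and row["parent_id"] == ""


class TestKmult:
    def test_star_tree_identity(self, star_tree):
        labels = tip_labels(star_tree)
        rng = np.random.default_rng(2)
        traits = pd.DataFrame(rng.normal(size=(len(labels), 3)), index=labels)
        r = kmult(star_tree, traits, n_iterations=99, seed=0)
        assert np.isclose(r.K, 1.0, atol=1e-10)

    def test_bm_traits_average_near_one(self):
        tree = gen_tree(32, seed=11)
        Ks = [
            kmult(tree, simulate_bm(tree, 3, 1.0, seed=s), n_iterations=0).K
            for s in range(60)
        ]
        assert 0.85 < np.mean(Ks) < 1.15

    def test_shuffled_traits_destroy_signal(self):
        tree = gen_tree(32, seed=11)
        traits = simulate_bm(tree, 3, 1.0, seed=5)
        obs = kmult(tree, traits, n_iterations=199, seed=1)
        rng = np.random.default_rng(0)
        shuffled = pd.DataFrame(
            traits.to_numpy()[rng.permutation(len(traits))], index=traits.index
        )
        null = kmult(tree, shuffled, n_iterations=199, seed=1)
        assert null.K < obs.K
        assert null.p_value > 0.05
        assert obs.p_value < 0.05

    def test_invariances(self, small_tree):
        labels = tip_labels(small_tree)
        traits = simulate_bm(small_tree, 4, 1.0, seed=3)
        base = kmult(small_tree, traits, n_iterations=0).K
        # branch-length scaling
        scaled = small_tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * 7.3
        assert np.isclose(kmult(scaled, traits, n_iterations=0).K, base, atol=1e-9)
        # orthogonal rotation of trait columns
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = pd.DataFrame(traits.to_numpy() @ Q, index=traits.index)
        assert np.isclose(kmult(small_tree, rotated, n_iterations=0).K, base,
                          atol=1e-9)

    def test_p_value_floor(self, small_tree):
        traits = simulate_bm(small_tree, 2, 1.0, seed=9)
        r = kmult(small_tree, traits, n_iterations=99, seed=0)
        assert r.p_value >= 1.0 / 100.0

    def test_permutation_p_uniform_under_null(self, small_tree):
        # iid (phylogeny-free) traits on a structured tree are exchangeable
        # across tips, so the permutation p-value should be near-uniform
        labels = tip_labels(small_tree)
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(40):
            traits = pd.DataFrame(
                rng.normal(size=(len(labels), 2)), index=labels
            )
            ps.append(kmult(small_tree, traits, n_iterations=49, seed=rep).p_value)
        assert 0.3 < np.mean(ps) < 0.7
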