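import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import wpcna
from wpcna import network as net
from wpcna.modules import (
    GREY,
    cut_dynamic_hybrid,
    cut_dynamic_tree,
    cut_static,
    eigenpeptide_dendrogram,
    mds_embed,
    module_eigenpeptides,
    module_membership,
    peptide_tree,
)


def nested_block_dissimilarity():
    """Two superblocks of two tight sub-blocks each (3-level structure)."""
    n = 40
    D = np.full((n, n), 1.0)
    for s in range(2):
        D[s * 20:(s + 1) * 20, s * 20:(s + 1) * 20] = 0.5
    for b in range(4):
        D[b * 10:(b + 1) * 10, b * 10:(b + 1) * 10] = 0.1
    np.fill_diagonal(D, 0.0)
    ids = [f"p{i:02d}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)


@pytest.fixture(scope="module")
def planted_network(small_study):
    X, _ = net.drop_unusable_peptides(small_study.intensities)
    S = net.similarity_matrix(X)
    TOM = net.tom_similarity(net.adjacency(S, 8))
    D = net.tom_dissimilarity(TOM)
    tree, ids = peptide_tree(D)
    return X, D, tree, ids, small_study.truth_modules


class TestPeptideTree:
    def test_two_blocks_split_at_height_one(self, two_block_dissimilarity):
        tree, ids = peptide_tree(two_block_dissimilarity)
        assert tree[-1, 2] == pytest.approx(1.0)
        assert set(fcluster(tree, 2, criterion="maxclust")) == {1, 2}

    def test_equal_dissimilarity_is_flat(self):
        D = np.full((6, 6), 0.7)
        np.fill_diagonal(D, 0.0)
        tree, _ = peptide_tree(D)
        assert np.allclose(tree[:, 2], 0.7)

    def test_deterministic_across_runs(self, rng):
        M = rng.random((10, 10))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        t1, _ = peptide_tree(D)
        t2, _ = peptide_tree(D)
        assert np.array_equal(t1, t2)

    def test_invalid_linkage_rejected(self, two_block_dissimilarity):
        with pytest.raises(ValueError):
            peptide_tree(two_block_dissimilarity, "ward")


class TestCuts:
    def test_static_two_blocks(self, two_block_dissimilarity):
        tree, ids = peptide_tree(two_block_dissimilarity)
        lab = cut_static(tree, ids, 0.5, min_size=2)
        assert set(lab.unique()) == {"turquoise", "blue"}
        assert (lab != GREY).all()

    def test_static_everything_grey_when_min_size_too_big(
        self, two_block_dissimilarity
    ):
        tree, ids = peptide_tree(two_block_dissimilarity)
        lab = cut_static(tree, ids, 0.5, min_size=11)
        assert (lab == GREY).all()

    def test_dynamic_agrees_with_static_on_separable_blocks(
        self, two_block_dissimilarity
    ):
        tree, ids = peptide_tree(two_block_dissimilarity)
        static = cut_static(tree, ids, 0.5, min_size=3)
        dynamic = cut_dynamic_tree(tree, ids, min_size=3)
        assert (static == dynamic).all()

    def test_deep_split_controls_nested_blocks(self):
        D = nested_block_dissimilarity()
        tree, ids = peptide_tree(D)
        shallow = cut_dynamic_tree(tree, ids, min_size=5, deep_split=0)
        deep = cut_dynamic_tree(tree, ids, min_size=5, deep_split=3)
        assert shallow.nunique() == 2  # superblocks only
        assert deep.nunique() == 4  # sub-blocks resolved

    def test_min_size_validation(self, two_block_dissimilarity):
        tree, ids = peptide_tree(two_block_dissimilarity)
        with pytest.raises(ValueError):
            cut_dynamic_tree(tree, ids, min_size=2)

    def test_hybrid_attaches_zero_distance_leaf(self):
        # 10-leaf tight block + 1 leaf at distance 0 to all members but
        # chained onto the tree via a grey-ish position
        n = 12
        D = np.full((n, n), 1.0)
        D[:10, :10] = 0.1
        D[10, :10] = 0.0
        D[:10, 10] = 0.0
        D[10, 10] = 0.0
        # leaf 11 is equidistant-far from everything
        np.fill_diagonal(D, 0.0)
        ids = [f"p{i}" for i in range(n)]
        Ddf = pd.DataFrame(D, index=ids, columns=ids)
        tree, ids = peptide_tree(Ddf)
        lab = cut_dynamic_hybrid(tree, ids, Ddf, min_size=5)
        assert lab["p10"] != GREY
        assert lab["p11"] == GREY

    def test_hybrid_assigns_at_least_as_many_as_dynamic(self, planted_network):
        X, D, tree, ids, truth = planted_network
        dynamic = cut_dynamic_tree(tree, ids)
        hybrid = cut_dynamic_hybrid(tree, ids, D)
        truth = truth.loc[dynamic.index]
        planted = truth != "none"

        def hits(lab):
            return int(((lab != GREY) & planted).sum())

        assert hits(hybrid) >= hits(dynamic)

    def test_planted_modules_recovered(self, planted_network):
        from sklearn.metrics import adjusted_rand_score

        X, D, tree, ids, truth = planted_network
        lab = cut_dynamic_hybrid(tree, ids, D)
        assert adjusted_rand_score(truth.loc[lab.index], lab) >= 0.6

    def test_largest_module_is_turquoise(self, planted_network):
        X, D, tree, ids, _ = planted_network
        lab = cut_dynamic_hybrid(tree, ids, D)
        sizes = lab[lab != GREY].value_counts()
        assert sizes.index[0] == "turquoise"
        assert sizes.iloc[0] == sizes.max()


class TestEigenpeptides:
    def test_identical_peptides_rank_one(self, rng):
        v = rng.standard_normal(12)
        X = pd.DataFrame([v, v, v], index=list("abc"),
                         columns=[f"s{i}" for i in range(12)])
        lab = pd.Series(["m", "m", "m"], index=list("abc"))
        ME, ve = module_eigenpeptides(X, lab)
        assert abs(np.corrcoef(ME.loc["m"], v)[0, 1]) == pytest.approx(1.0)
        assert ve["m"] == pytest.approx(1.0)

    def test_anticorrelated_pair_still_rank_one(self, rng):
        x = rng.standard_normal(10)
        X = pd.DataFrame([x, -x], index=list("ab"),
                         columns=[f"s{i}" for i in range(10)])
        lab = pd.Series(["m", "m"], index=list("ab"))
        ME, ve = module_eigenpeptides(X, lab)
        assert abs(np.corrcoef(ME.loc["m"], x)[0, 1]) == pytest.approx(1.0)
        assert ve["m"] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 20)),
                         index=[f"p{i}" for i in range(30)],
                         columns=[f"s{i}" for i in range(20)])
        lab = pd.Series("m", index=X.index)
        ME, ve = module_eigenpeptides(X, lab)
        # oracle: leading eigenvector of Z^T Z of the standardized block
        Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
        G = Z.to_numpy().T @ Z.to_numpy()
        w, V = np.linalg.eigh(G)
        pc1 = V[:, -1]
        assert abs(np.corrcoef(ME.loc["m"], pc1)[0, 1]) == pytest.approx(
            1.0, abs=1e-10
        )
        assert ve["m"] == pytest.approx(w[-1] / w.sum(), abs=1e-10)

    def test_invariant_to_peptide_order_up_to_sign(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 10)),
                         index=[f"p{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(10)])
        lab = pd.Series("m", index=X.index)
        ME1, _ = module_eigenpeptides(X, lab)
        perm = X.sample(frac=1.0, random_state=1)
        ME2, _ = module_eigenpeptides(perm, lab.loc[perm.index])
        r = np.corrcoef(ME1.loc["m"], ME2.loc["m"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_zero_mean_scores(self, rng):
        X = pd.DataFrame(rng.standard_normal((5, 9)),
                         index=list("abcde"),
                         columns=[f"s{i}" for i in range(9)])
        ME, _ = module_eigenpeptides(X, pd.Series("m", index=X.index))
        assert ME.loc["m"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_singleton_module_warns(self, rng):
        X = pd.DataFrame(rng.standard_normal((1, 8)), index=["p"],
                         columns=[f"s{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="single peptide"):
            ME, ve = module_eigenpeptides(X, pd.Series("m", index=["p"]))
        assert ve["m"] == 1.0


class TestMembership:
    def test_peptide_equal_to_eigenpeptide(self, rng):
        me = rng.standard_normal(10)
        X = pd.DataFrame([me, rng.standard_normal(10)], index=list("ab"),
                         columns=[f"s{i}" for i in range(10)])
        ME = pd.DataFrame([me], index=["m"], columns=X.columns)
        kME = module_membership(X, ME)
        assert kME.loc["a", "m"] == pytest.approx(1.0)

    def test_own_module_membership_dominates_on_planted_data(
        self, planted_network
    ):
        X, D, tree, ids, _ = planted_network
        lab = cut_dynamic_hybrid(tree, ids, D)
        ME, _ = module_eigenpeptides(X, lab)
        kME = module_membership(X, ME)
        own, other = [], []
        for pid, m in lab.items():
            if m == GREY:
                continue
            own.append(abs(kME.loc[pid, m]))
            other.extend(abs(kME.loc[pid, o]) for o in ME.index if o != m)
        assert np.mean(own) > np.mean(other)


class TestEigenpeptideDendrogram:
    def test_identical_modules_merge_at_zero(self, rng):
        v = rng.standard_normal(10)
        ME = pd.DataFrame([v, v], index=["a", "b"],
                          columns=[f"s{i}" for i in range(10)])
        Z, _ = eigenpeptide_dendrogram(ME)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_modules_merge_at_two(self, rng):
        v = rng.standard_normal(10)
        ME = pd.DataFrame([v, -v], index=["a", "b"],
                          columns=[f"s{i}" for i in range(10)])
        Z, _ = eigenpeptide_dendrogram(ME)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_planted_correlated_pair_merges_first(self, rng):
        base = rng.standard_normal(40)
        pair1 = base
        pair2 = 0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(40)
        ME = pd.DataFrame(
            [pair1, pair2, rng.standard_normal(40), rng.standard_normal(40)],
            index=["a", "b", "c", "d"],
            columns=[f"s{i}" for i in range(40)],
        )
        Z, labels = eigenpeptide_dendrogram(ME)
        first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
        assert first == {"a", "b"}


class TestMDS:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3))
        np.fill_diagonal(D, 0.0)
        Y = mds_embed(D, dims=2).to_numpy()
        dists = [np.linalg.norm(Y[i] - Y[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, dists[0])

    def test_collinear_points_second_axis_vanishes(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        D = np.abs(x[:, None] - x[None, :])
        Y = mds_embed(D, dims=1).to_numpy()
        d_embedded = np.abs(Y[:, 0][:, None] - Y[:, 0][None, :])
        assert np.allclose(d_embedded, D, atol=1e-8)

    def test_euclidean_input_reproduced_exactly(self, rng):
        P = rng.standard_normal((20, 2))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        Y = mds_embed(D, dims=2).to_numpy()
        D2 = np.linalg.norm(Y[:, None] - Y[None, :], axis=-1)
        assert np.max(np.abs(D - D2)) < 1e-8

    def test_dims_beyond_rank_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        D = np.abs(x[:, None] - x[None, :])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            mds_embed(D, dims=2)
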