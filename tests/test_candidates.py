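import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wpcna
from wpcna.candidates import (
    cumulative_distance,
    cumulative_distance_table,
    export_tom_edges,
    group_de,
    integrative_rank,
    rank_candidate_peptides,
)
from wpcna.network import tom_similarity


class TestCumulativeDistance:
    @pytest.mark.parametrize(
        "i0, means, expected",
        [
            (4.0, (4.0, 4.0, 4.0), 0.0),
            (5.0, (4.0, 3.0, 2.0), 6.0),
            (3.0, (4.0, 4.0, 4.0), -3.0),
        ],
    )
    def test_hand_worked_values(self, i0, means, expected):
        assert cumulative_distance(i0, *means) == pytest.approx(expected)

    def test_linearity(self, rng):
        vals = rng.standard_normal(4)
        assert cumulative_distance(*(2 * vals)) == pytest.approx(
            2 * cumulative_distance(*vals)
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cumulative_distance(np.nan, 1.0, 1.0, 1.0)


class TestCumulativeDistanceTable:
    def test_table_identity_and_focal_exclusion(self, small_study):
        X = small_study.intensities
        focal = "rTg4510-blast-1"
        tab = cumulative_distance_table(X, small_study.metadata, focal)
        expected = 3 * tab["i0"] - (tab["mean_bt"] + tab["mean_st"] + tab["mean_sn"])
        assert np.allclose(tab["cumdist"], expected, equal_nan=True)
        # focal excluded from its own (blast-transgenic) group mean
        peers = [
            a for a in small_study.metadata.index[
                small_study.metadata["group"] == "rTg4510-blast"
            ]
            if a != focal
        ]
        pid = tab.index[0]
        assert tab.loc[pid, "mean_bt"] == pytest.approx(
            X.loc[pid, peers].mean()
        )

    def test_missing_focal_peptides_skipped(self, small_study):
        X = small_study.intensities.copy()
        focal = "nc-sham-1"
        X.iloc[0, X.columns.get_loc(focal)] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            tab = cumulative_distance_table(X, small_study.metadata, focal)
        assert X.index[0] not in tab.index


class TestRankCandidates:
    def make_table(self, cumdists, ids=None):
        ids = ids or [f"p{i}" for i in range(len(cumdists))]
        cd = pd.Series(cumdists, index=ids)
        return pd.DataFrame(
            {"i0": 0.0, "mean_bt": 0.0, "mean_st": 0.0, "mean_sn": 0.0,
             "cumdist": cd, "abs_cumdist": cd.abs()}
        )

    def test_dominant_peptide_ranks_first(self):
        tab = self.make_table([0.1, -9.0, 0.2])
        lab = pd.Series("m", index=tab.index)
        out = rank_candidate_peptides(tab, lab, ["m"], top_n=2)
        assert out.index[0] == "p1"
        assert out["direction"].iloc[0] == "decreased"

    def test_ties_broken_lexicographically(self):
        tab = self.make_table([1.0, 1.0, 1.0], ids=["c", "a", "b"])
        lab = pd.Series("m", index=tab.index)
        out = rank_candidate_peptides(tab, lab, ["m"], top_n=3)
        assert list(out.index) == ["a", "b", "c"]

    def test_restricted_to_modules_of_interest(self):
        tab = self.make_table([5.0, 1.0])
        lab = pd.Series(["other", "m"], index=tab.index)
        out = rank_candidate_peptides(tab, lab, ["m"], top_n=5)
        assert list(out.index) == ["p1"]

    def test_planted_deviant_peptides_recovered(self):
        """A focal animal spiked +3 SD on 10 peptides is found in the top 10."""
        hits = []
        for seed in range(5):
            study = wpcna.simulate_study(
                n_peptides=200, module_sizes=(50,), seed=seed,
                missing_rate=0.0,
            )
            X = study.intensities.copy()
            focal = "rTg4510-blast-1"
            spiked = list(X.index[:10])  # inside module m1
            X.loc[spiked, focal] += 3.0 * study.config.noise_sd
            tab = cumulative_distance_table(X, study.metadata, focal)
            out = rank_candidate_peptides(
                tab, study.truth_modules, ["m1"], top_n=10
            )
            hits.append(len(set(out.index) & set(spiked)))
        assert np.mean(hits) >= 9


class TestGroupDE:
    def test_identical_groups_null(self):
        """Groups with the same values give zero fold change and p = 1."""
        md = pd.DataFrame(
            {"group": ["g1"] * 4 + ["g2"] * 4},
            index=[f"a{i}" for i in range(8)],
        )
        rng = np.random.default_rng(2)
        half = rng.standard_normal((10, 4))
        X = pd.DataFrame(np.hstack([half, half]),
                         index=[f"p{i}" for i in range(10)],
                         columns=md.index)
        de = group_de(X, md, ("g1", "g2"))
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["p_value"], 1.0)

    def test_label_swap_negates_fold_change(self, small_study):
        X = small_study.intensities.head(30)
        md = small_study.metadata
        de1 = group_de(X, md, ("rTg4510-blast", "nc-sham"))
        de2 = group_de(X, md, ("nc-sham", "rTg4510-blast"))
        assert np.allclose(de1["log2fc"], -de2["log2fc"], equal_nan=True)
        assert np.allclose(de1["p_value"], de2["p_value"], equal_nan=True)

    def test_constant_shift_degenerate_t_flagged(self):
        md = pd.DataFrame(
            {"group": ["g1"] * 3 + ["g2"] * 3},
            index=[f"a{i}" for i in range(6)],
        )
        X = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], index=["p"], columns=md.index
        )
        de = group_de(X, md, ("g1", "g2"))
        assert de.loc["p", "p_value"] == 0.0
        assert de.loc["p", "flag"] == "zero_variance"
        assert de.loc["p", "log2fc"] == pytest.approx(-1.0)

    def test_power_matches_pooled_t_closed_form(self):
        """Empirical power at delta=1, sd=1, 5v5 matches the noncentral-t value."""
        rng = np.random.default_rng(12)
        md = pd.DataFrame(
            {"group": ["g1"] * 5 + ["g2"] * 5},
            index=[f"a{i}" for i in range(10)],
        )
        A = rng.standard_normal((1000, 5)) + 1.0
        B = rng.standard_normal((1000, 5))
        X = pd.DataFrame(np.hstack([A, B]),
                         index=[f"p{i}" for i in range(1000)],
                         columns=md.index)
        de = group_de(X, md, ("g1", "g2"))
        power = (de["p_value"] < 0.05).mean()
        nc = 1.0 / np.sqrt(1 / 5 + 1 / 5)
        tcrit = stats.t.ppf(0.975, df=8)
        analytic = (
            stats.nct.sf(tcrit, df=8, nc=nc) + stats.nct.cdf(-tcrit, df=8, nc=nc)
        )
        assert power == pytest.approx(analytic, abs=0.05)

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(3)
        md = pd.DataFrame(
            {"group": ["g1"] * 5 + ["g2"] * 5},
            index=[f"a{i}" for i in range(10)],
        )
        X = pd.DataFrame(rng.standard_normal((1000, 10)),
                         index=[f"p{i}" for i in range(1000)],
                         columns=md.index)
        de = group_de(X, md, ("g1", "g2"))
        ks = stats.kstest(de["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestIntegrativeRank:
    def make_de(self, fcs, ps, ids=None):
        ids = ids or [f"p{i}" for i in range(len(fcs))]
        return pd.DataFrame({"log2fc": fcs, "p_value": ps}, index=ids)

    def test_hand_worked_single_contrast(self):
        de = {"c1": self.make_de([2.0, 1.0], [1e-3, 1e-1])}
        out = integrative_rank(de, ["p0", "p1"], require_five=False)
        assert out.loc["p0", "integrative_rank"] == 2.0
        assert out.loc["p1", "integrative_rank"] == 4.0
        assert out.index[0] == "p0"

    def test_identical_statistics_tie_everywhere(self):
        de = {f"c{i}": self.make_de([1.0] * 3, [0.5] * 3) for i in range(5)}
        out = integrative_rank(de, ["p0", "p1", "p2"])
        assert out["integrative_rank"].nunique() == 1
        assert list(out.index) == ["p0", "p1", "p2"]

    def test_permutation_invariance(self, rng):
        ids = [f"p{i}" for i in range(20)]
        de = {
            f"c{i}": self.make_de(
                rng.standard_normal(20), rng.uniform(size=20), ids
            )
            for i in range(5)
        }
        out1 = integrative_rank(de, ids)
        out2 = integrative_rank(de, list(reversed(ids)))
        pd.testing.assert_series_equal(
            out1["integrative_rank"].sort_index(),
            out2["integrative_rank"].sort_index(),
        )

    def test_rank_depends_only_on_p_value_order(self, rng):
        ids = [f"p{i}" for i in range(10)]
        fcs = rng.standard_normal(10)
        ps = rng.uniform(size=10)
        de1 = {f"c{i}": self.make_de(fcs, ps, ids) for i in range(5)}
        de2 = {f"c{i}": self.make_de(fcs, ps**3, ids) for i in range(5)}
        pd.testing.assert_frame_equal(
            integrative_rank(de1, ids), integrative_rank(de2, ids)
        )

    def test_wrong_contrast_count_rejected(self):
        de = {"c1": self.make_de([1.0], [0.5], ["p0"])}
        with pytest.raises(ValueError, match="5 contrasts"):
            integrative_rank(de, ["p0"])


class TestExportEdges:
    def test_identity_tom_has_no_edges(self):
        TOM = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        lab = pd.Series("m", index=TOM.index)
        assert export_tom_edges(TOM, lab).empty

    def test_three_node_example_strict_threshold(self):
        A = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        TOM = tom_similarity(A)
        lab = pd.Series("m", index=TOM.index)
        edges = export_tom_edges(TOM, lab, threshold=0.5)
        pairs = {tuple(sorted(p)) for p in zip(edges["source"], edges["target"])}
        assert ("a", "b") in pairs
        assert ("b", "c") not in pairs  # TOM = 0.5 exactly, strict >

    def test_zero_threshold_gives_all_pairs(self, rng):
        n = 6
        M = rng.uniform(0.01, 1.0, size=(n, n))
        TOM = pd.DataFrame((M + M.T) / 2, index=range(n), columns=range(n))
        lab = pd.Series("m", index=TOM.index)
        edges = export_tom_edges(TOM, lab, threshold=0.0)
        assert len(edges) == n * (n - 1) // 2
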