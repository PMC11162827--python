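"""Rarefaction, Bray-Curtis, PERMANOVA, SIMPER and the decomposer screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakesip import DesignSpec, community as cm, default_truth
from lakesip.simulate import DEFAULT_DECOMPOSERS, generate_community


def _toy_counts():
    rng = np.random.default_rng(0)
    counts = rng.integers(50, 500, size=(6, 8))
    return pd.DataFrame(
        counts, index=[f"g{i}" for i in range(6)], columns=[f"b{j}" for j in range(8)]
    )


class TestRarefy:
    def test_totals_exactly_depth(self):
        otu = _toy_counts()
        out = cm.rarefy(otu, depth=500, seed=1)
        assert (out.sum(axis=0) == 500).all()
        assert (out <= otu).all().all()

    def test_depth_equal_total_unchanged(self):
        otu = pd.DataFrame({"b1": [60, 30, 10]}, index=["g1", "g2", "g3"])
        out = cm.rarefy(otu, depth=100, seed=0)
        pd.testing.assert_frame_equal(out, otu)

    def test_shallow_bottle_dropped_with_warning(self):
        otu = pd.DataFrame({"deep": [600, 400], "shallow": [5, 5]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="shallow"):
            out = cm.rarefy(otu, depth=100, seed=0)
        assert list(out.columns) == ["deep"]

    def test_deterministic_given_seed(self):
        otu = _toy_counts()
        a = cm.rarefy(otu, depth=300, seed=42)
        b = cm.rarefy(otu, depth=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_expected_proportion_preserved(self):
        # hypergeometric expectation: post-rarefaction proportion is unbiased
        otu = pd.DataFrame({"b1": [600, 300, 100]}, index=["g1", "g2", "g3"])
        props = [
            cm.rarefy(otu, depth=100, seed=s).loc["g1", "b1"] / 100.0 for s in range(200)
        ]
        p = 0.6
        # per-draw SD of a hypergeometric proportion at n=100 of N=1000
        sd = np.sqrt(p * (1 - p) * (1000 - 100) / (100 * 999))
        se = sd / np.sqrt(200)
        assert abs(np.mean(props) - p) < 2 * se


class TestFilterAbundance:
    def test_toy_threshold(self):
        # 3 genera at 60/39/1 reads in each of 10 bottles -> 1% genus kept,
        # 0.1%-of-total genus removed... global shares are 60%, 39%, 1%;
        # with threshold 0.5% all three stay, with threshold 2% one drops
        otu = pd.DataFrame(
            np.tile([[60], [39], [1]], 10), index=["g1", "g2", "g3"],
            columns=[f"b{j}" for j in range(10)],
        )
        kept = cm.filter_abundance(otu, global_threshold_pct=0.5)
        assert list(kept.index) == ["g1", "g2", "g3"]
        kept2 = cm.filter_abundance(otu, global_threshold_pct=2.0)
        assert list(kept2.index) == ["g1", "g2"]
        # contributions are % of the bottle total
        assert kept2["b0"].tolist() == [60.0, 39.0]

    def test_all_above_threshold_identity(self):
        otu = pd.DataFrame({"b1": [50, 50], "b2": [30, 70]}, index=["g1", "g2"])
        out = cm.filter_abundance(otu)
        assert out.shape == otu.shape
        assert out["b2"].tolist() == [30.0, 70.0]

    def test_empty_result_rejected(self):
        otu = pd.DataFrame({"b1": [1, 1]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="every genus"):
            cm.filter_abundance(otu, global_threshold_pct=60.0)


class TestBrayCurtis:
    def test_identical_bottles_zero(self):
        t = pd.DataFrame({"b1": [50.0, 50.0], "b2": [50.0, 50.0]}, index=["g1", "g2"])
        dm = cm.braycurtis_matrix(t)
        assert dm.loc["b1", "b2"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(dm), 0.0)

    def test_disjoint_bottles_one(self):
        t = pd.DataFrame({"b1": [100.0, 0.0], "b2": [0.0, 100.0]}, index=["g1", "g2"])
        assert cm.braycurtis_matrix(t).loc["b1", "b2"] == pytest.approx(1.0)

    def test_hand_computed_pair_untransformed(self):
        # BC([0.7,0.3],[0.3,0.7]) = (0.4+0.4)/2 = 0.4
        t = pd.DataFrame({"b1": [0.7, 0.3], "b2": [0.3, 0.7]}, index=["g1", "g2"])
        dm = cm.braycurtis_matrix(t, sqrt_transform=False)
        assert dm.loc["b1", "b2"] == pytest.approx(0.4, rel=1e-9)

    def test_sqrt_transform_changes_distance(self):
        t = pd.DataFrame({"b1": [81.0, 19.0], "b2": [19.0, 81.0]}, index=["g1", "g2"])
        plain = cm.braycurtis_matrix(t, sqrt_transform=False).loc["b1", "b2"]
        rooted = cm.braycurtis_matrix(t, sqrt_transform=True).loc["b1", "b2"]
        a, b = np.sqrt([81.0, 19.0]), np.sqrt([19.0, 81.0])
        assert rooted == pytest.approx(np.abs(a - b).sum() / (a + b).sum(), rel=1e-9)
        assert rooted != pytest.approx(plain)

    def test_all_zero_bottle_rejected(self):
        t = pd.DataFrame({"b1": [1.0, 1.0], "b2": [0.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            cm.braycurtis_matrix(t)


class TestPermanova:
    def _euclid(self, x):
        return np.abs(np.subtract.outer(x, x))

    def test_univariate_euclidean_equals_anova_f(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=15)
        groups = np.repeat(["a", "b", "c"], 5)
        res = cm.permanova(self._euclid(x), groups, n_perm=99, seed=0)
        f_anova = stats.f_oneway(x[:5], x[5:10], x[10:]).statistic
        assert res.statistic == pytest.approx(f_anova, rel=1e-9)

    def test_matches_skbio_pseudo_f(self):
        # independent oracle: scikit-bio's PERMANOVA on the same distances
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        groups = np.repeat(["a", "b", "c"], 4)
        mine = cm.permanova(d, groups, n_perm=99, seed=0)
        ids = [str(i) for i in range(12)]
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d, ids), list(groups), permutations=99
        )
        assert mine.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_separated_groups_minimal_p(self):
        # groups of 8 so a random permutation essentially never reproduces
        # the observed partition: p attains its floor of 1/(n_perm + 1)
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.1, 8), rng.normal(10, 0.1, 8)])
        res = cm.permanova(self._euclid(x), np.repeat(["a", "b"], 8), n_perm=999, seed=0)
        assert res.p_value <= 0.001

    def test_type_i_error_calibrated_and_p_uniform(self):
        # 500 null simulations: rejection rate 0.05 +- 0.02 at alpha = 0.05,
        # p-values indistinguishable from uniform (KS p > 0.01)
        rng = np.random.default_rng(7)
        groups = np.repeat(["a", "b", "c"], 4)
        pvals = []
        for i in range(500):
            x = rng.normal(size=(12, 5))
            from scipy.spatial.distance import pdist, squareform

            d = squareform(pdist(x))
            pvals.append(cm.permanova(d, groups, n_perm=199, seed=i).p_value)
        pvals = np.asarray(pvals)
        assert abs((pvals <= 0.05).mean() - 0.05) <= 0.02
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_determinism_and_degenerate_grouping(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        d = self._euclid(x)
        g = np.repeat(["a", "b"], 5)
        assert (
            cm.permanova(d, g, n_perm=199, seed=3).p_value
            == cm.permanova(d, g, n_perm=199, seed=3).p_value
        )
        with pytest.raises(ValueError):
            cm.permanova(d, ["a"] * 10, n_perm=99)
        with pytest.raises(ValueError):
            cm.permanova(d, ["a"] * 9 + ["b"], n_perm=99)


def _brute_force_simper(table, a_cols, b_cols):
    """Oracle: average per-taxon Bray-Curtis share over all between pairs."""
    contrib = np.zeros(len(table))
    pairs = 0
    for ca in a_cols:
        for cb in b_cols:
            x, y = table[ca].to_numpy(), table[cb].to_numpy()
            contrib += np.abs(x - y) / (x + y).sum()
            pairs += 1
    return contrib / pairs


class TestSimper:
    def test_identical_groups_zero(self):
        t = pd.DataFrame(
            {"a1": [50.0, 50.0], "a2": [50.0, 50.0], "b1": [50.0, 50.0], "b2": [50.0, 50.0]},
            index=["g1", "g2"],
        )
        out = cm.simper(t, ["A", "A", "B", "B"])
        assert out["contribution"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_differing_taxon_contributes_all(self):
        t = pd.DataFrame(
            {"a1": [80.0, 20.0], "a2": [80.0, 20.0], "b1": [60.0, 20.0], "b2": [60.0, 20.0]},
            index=["g1", "g2"],
        )
        out = cm.simper(t, ["A", "A", "B", "B"])
        top = out.iloc[0]
        assert top["taxon"] == "g1"
        assert top["contribution_pct"] == pytest.approx(100.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame(
            rng.uniform(0, 30, size=(3, 7)),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(7)],
        )
        groups = ["A"] * 3 + ["B"] * 4
        out = cm.simper(t, groups).set_index("taxon")["contribution"]
        oracle = _brute_force_simper(t, ["s0", "s1", "s2"], ["s3", "s4", "s5", "s6"])
        for g, expected in zip(["g1", "g2", "g3"], oracle):
            assert out[g] == pytest.approx(expected, rel=1e-9)

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        rng = np.random.default_rng(10)
        t = pd.DataFrame(
            rng.uniform(0, 30, size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = ["A"] * 4 + ["B"] * 4
        out = cm.simper(t, groups)
        dm = cm.braycurtis_matrix(t, sqrt_transform=False)
        between = dm.iloc[:4, 4:].to_numpy().mean()
        assert out["contribution"].sum() == pytest.approx(between, rel=1e-9)
        assert out["contribution"].sum() == pytest.approx(
            out.attrs["mean_dissimilarity"], rel=1e-12
        )

    def test_three_groups_pairwise(self):
        t = _toy_counts().astype(float)
        out = cm.simper(t, ["A", "A", "B", "B", "C", "C", "C", "C"])
        assert set(out) == {("A", "B"), ("A", "C"), ("B", "C")}


class TestDecomposerScreen:
    @staticmethod
    def _rates_frame(design, truth):
        rates_map = truth.cells.set_index(["lake", "season", "substrate"])[
            "decomposition_rate"
        ]
        rows = [
            {"bottle": r.bottle, "decomposition": rates_map.loc[(r.lake, r.season, r.substrate)]}
            for r in design.bottles().itertuples(index=False)
            if r.substrate != "control"
        ]
        return pd.DataFrame(rows)

    def test_planted_decomposers_recovered_with_high_sensitivity(self):
        design = DesignSpec(seed=0)
        truth = default_truth(design)
        meta = design.bottles()
        rates = self._rates_frame(design, truth)
        ps_genera = [g for g, (_, _, sub) in DEFAULT_DECOMPOSERS.items() if sub == "PS"]
        hits, total, null_hits, null_total = 0, 0, 0, 0
        for seed in range(5):
            otu, _ = generate_community(design, DEFAULT_DECOMPOSERS, truth=truth, seed=seed)
            table = cm.filter_abundance(cm.rarefy(otu, seed=seed))
            screen = cm.decomposer_screen(table, meta, rates, substrate="PS")
            planted = screen[screen["genus"].isin(ps_genera)]
            hits += int(planted["passes"].sum())
            total += len(planted)
            nulls = screen[~screen["genus"].isin(ps_genera)]
            null_hits += int(nulls["passes"].sum())
            null_total += len(nulls)
        assert hits / total >= 0.9
        assert null_hits / null_total <= 0.1

    def test_null_coupling_rarely_passes(self):
        # no planted decomposers at all: pass rate stays below 10%
        design = DesignSpec(seed=0)
        truth = default_truth(design)
        meta = design.bottles()
        rates = self._rates_frame(design, truth)
        hits, total = 0, 0
        for seed in range(10):
            otu, _ = generate_community(design, {}, truth=truth, seed=100 + seed)
            table = cm.filter_abundance(cm.rarefy(otu, seed=seed))
            screen = cm.decomposer_screen(table, meta, rates, substrate="PS")
            hits += int(screen["passes"].sum())
            total += len(screen)
        assert hits / total <= 0.1

    def test_abundance_gate_excludes_rare_genus(self):
        # perfect rank correlation but only 1.5% abundance -> fails
        meta = pd.DataFrame(
            [
                {"bottle": f"b{i}", "lake": lake, "season": "summer", "substrate": "PS"}
                for i, lake in enumerate(["L1"] * 2 + ["L2"] * 2 + ["L3"] * 2)
            ]
        )
        rates = pd.DataFrame(
            {"bottle": [f"b{i}" for i in range(6)], "decomposition": [1, 1, 2, 2, 3, 3]}
        )
        table = pd.DataFrame(
            {
                f"b{i}": [1.0 + 0.1 * i, 99.0 - 0.1 * i]
                for i in range(6)
            },
            index=["rare_but_correlated", "dominant"],
        )
        screen = cm.decomposer_screen(table, meta, rates, substrate="PS")
        row = screen[screen["genus"] == "rare_but_correlated"].iloc[0]
        assert row["spearman_rho"] > 0.6
        assert not row["passes"]

    def test_constant_abundance_skipped_with_warning(self):
        meta = pd.DataFrame(
            [
                {"bottle": f"b{i}", "lake": f"L{i % 3}", "season": "summer", "substrate": "PS"}
                for i in range(6)
            ]
        )
        rates = pd.DataFrame(
            {"bottle": [f"b{i}" for i in range(6)], "decomposition": [1, 1, 2, 2, 3, 3]}
        )
        table = pd.DataFrame(
            {f"b{i}": [5.0, 90.0 + i] for i in range(6)}, index=["flat", "varying"]
        )
        with pytest.warns(UserWarning, match="constant abundance"):
            screen = cm.decomposer_screen(table, meta, rates, substrate="PS")
        assert "flat" not in set(screen["genus"])


def test_nmds_ordination_smoke():
    rng = np.random.default_rng(11)
    t = pd.DataFrame(
        rng.uniform(1, 30, size=(6, 10)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(10)],
    )
    coords = cm.nmds_ordination(cm.braycurtis_matrix(t))
    assert coords.shape == (10, 2)
    assert "stress" in coords.attrs
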