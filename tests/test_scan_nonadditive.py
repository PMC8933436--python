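"""Midparent residuals, dominance and interaction scans, hub resolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import diplomap as dm
from diplomap.scan_nonadditive import (
    classify_dominance,
    dominance_permutation_threshold,
    dominance_scan,
    effect_and_dominance,
    find_hubs,
    hub_forward_scan,
    marker_pvalues_3class,
    midparent_residuals,
    pair_interaction_pvalues,
    pairwise_scan,
    remove_pairs_near_hub,
    resolve_hub,
    threeway_scan,
    trio_interaction_pvalues,
)


@pytest.fixture(scope="module")
def nonadditive_study(small_panel):
    """Planted dominance locus and two interactions (a x a, d x d)."""
    arch = dm.TraitArchitecture(
        additive={10: 0.05, 40: 0.03},
        dominance={40: 0.06},
        interactions=[
            dm.Interaction(70, 100, aa=0.06),
            dm.Interaction(20, 55, dd=0.10),
        ],
        noise_sd=0.05,
    )
    y = dm.simulate_phenotypes(small_panel, arch, seed=12)
    return small_panel, y, midparent_residuals(y, small_panel)


class TestMidparentResiduals:
    def test_phenotype_equal_to_midparent_gives_zero_residuals(self, small_panel):
        # a purely parent-additive phenotype: y = sum of parental values
        rng = np.random.default_rng(41)
        pa = rng.normal(0, 1, small_panel.mata_parent.max() + 1)
        po = rng.normal(0, 1, small_panel.matalpha_parent.max() + 1)
        y = 0.5 * (pa[small_panel.mata_parent] + po[small_panel.matalpha_parent])
        res = midparent_residuals(y, small_panel)
        assert np.all(np.abs(res.values) < 1e-10)

    def test_residuals_orthogonal_to_midparent(self, nonadditive_study):
        _, _, res = nonadditive_study
        assert abs(np.corrcoef(res.values, res.midparent[res.mask])[0, 1]) < 1e-10
        assert abs(res.values.mean()) < 1e-10

    def test_additive_trait_leaves_little_residual_variance(self, small_panel):
        rng = np.random.default_rng(42)
        qtl = rng.choice(small_panel.mmap.n_markers, 8, replace=False)
        arch = dm.TraitArchitecture(
            additive={int(j): 0.05 for j in qtl}, noise_sd=0.0
        )
        y = dm.simulate_phenotypes(small_panel, arch, seed=43)
        res = midparent_residuals(y, small_panel)
        assert res.values.var() < 0.35 * y[res.mask].var()

    def test_low_offspring_parents_excluded(self, small_panel):
        y = np.full(small_panel.n_diploids, np.nan)
        members = np.concatenate(
            [small_panel.family_members(f) for f in range(5)]
        )
        y[members] = 1.0
        res = midparent_residuals(y, small_panel, min_offspring=20)
        # MATalpha parents now have only 5 phenotyped offspring each
        assert res.mask.sum() == 0


class TestDominanceScan:
    def test_single_marker_p_equals_one_way_anova(self, nonadditive_study):
        panel, _, res = nonadditive_study
        y = res.values
        G = panel.genotypes[res.mask]
        pvals = marker_pvalues_3class(y, G, min_class=1)
        for j in (20, 40, 90):
            groups = [y[G[:, j] == k] for k in (0, 1, 2)]
            p = stats.f_oneway(*groups).pvalue
            assert pvals[j] == pytest.approx(p, rel=1e-8)

    def test_planted_dominance_locus_detected(self, nonadditive_study):
        panel, _, res = nonadditive_study
        thr = dominance_permutation_threshold(res, panel, n_perm=300, seed=44)
        sc = dominance_scan(res, panel, threshold=thr)
        assert 40 in sc.detections["marker"].tolist()

    def test_purely_additive_trait_rarely_yields_dominance_detections(self, small_panel):
        """Additive-only traits clear the dominance scan in ~95% of null draws."""
        rng = np.random.default_rng(45)
        qtl = rng.choice(small_panel.mmap.n_markers, 6, replace=False)
        effects = {int(j): 0.05 for j in qtl}
        arch = dm.TraitArchitecture(additive=effects, noise_sd=0.05)
        y0 = dm.simulate_phenotypes(small_panel, arch, seed=46)
        res0 = midparent_residuals(y0, small_panel)
        thr = dominance_permutation_threshold(res0, small_panel, n_perm=300, seed=47)
        g = arch.genetic_values(small_panel)
        n_sim, false_pos = 40, 0
        for b in range(n_sim):
            y = g + rng.normal(0, 0.05, g.size)
            res = midparent_residuals(y, small_panel)
            p = marker_pvalues_3class(res.values, small_panel.genotypes[res.mask])
            false_pos += np.nanmin(p) < thr
        # binomial slack around the nominal 5% family-wise rate
        assert false_pos <= 6

    def test_shuffled_residuals_control_type_one_error(self, nonadditive_study):
        panel, _, res = nonadditive_study
        thr = dominance_permutation_threshold(res, panel, n_perm=400, seed=48)
        rng = np.random.default_rng(49)
        hits = 0
        n_sim = 200
        y = res.values.copy()
        G = panel.genotypes[res.mask]
        for _ in range(n_sim):
            rng.shuffle(y)
            p = marker_pvalues_3class(y, G)
            hits += np.nanmin(p) < thr
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(hits / n_sim - 0.05) < 3.5 * se


class TestDegreeOfDominance:
    def test_additive_locus_zero_degree(self, small_panel):
        g = small_panel.genotypes[:, 7].astype(float)
        eff = effect_and_dominance(g - 1.0, small_panel, 7)  # means (-1, 0, 1)
        assert eff.additive == pytest.approx(1.0)
        assert eff.dominance == pytest.approx(0.0)
        assert eff.degree == pytest.approx(0.0)
        assert eff.label == "incomplete_fit"

    def test_complete_dominance(self, small_panel):
        g = small_panel.genotypes[:, 7]
        y = np.where(g >= 1, 1.0, 0.0)  # means (0, 1, 1)
        eff = effect_and_dominance(y, small_panel, 7)
        assert (eff.additive, eff.dominance) == (0.5, 0.5)
        assert eff.degree == pytest.approx(1.0)
        assert eff.label == "complete_fit"

    def test_overdominance(self, small_panel):
        g = small_panel.genotypes[:, 7]
        y = np.select([g == 0, g == 1, g == 2], [0.0, 1.2, 1.0])
        eff = effect_and_dominance(y, small_panel, 7)
        assert eff.dominance == pytest.approx(0.7)
        assert eff.degree == pytest.approx(1.4)
        assert eff.label == "overdominant"

    @pytest.mark.parametrize(
        "degree,label",
        [
            (0.0, "incomplete_fit"),
            (0.89, "incomplete_fit"),
            (0.9, "complete_fit"),
            (1.1, "complete_fit"),
            (1.1000001, "overdominant"),
            (-0.89, "incomplete_deleterious"),
            (-0.9, "complete_deleterious"),
            (-1.1, "complete_deleterious"),
            (-1.2, "underdominant"),
        ],
    )
    def test_classification_band_edges(self, degree, label):
        assert classify_dominance(degree, d=degree) == label

    def test_zero_additive_effect_flagged(self, small_panel):
        g = small_panel.genotypes[:, 7]
        y = (g == 1).astype(float)  # pure dominance, a = 0
        eff = effect_and_dominance(y, small_panel, 7)
        assert np.isnan(eff.degree)
        assert eff.label == "overdominant"


class TestPairwiseScan:
    def test_interaction_p_equals_two_way_anova(self, nonadditive_study):
        panel, _, res = nonadditive_study
        y = res.values
        G = panel.genotypes[res.mask]
        out = pair_interaction_pvalues(y, G, np.array([[20, 55], [10, 70]]))
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for _, row in out.iterrows():
            df = pd.DataFrame(
                {
                    "y": y,
                    "g1": pd.Categorical(G[:, int(row["i"])]),
                    "g2": pd.Categorical(G[:, int(row["j"])]),
                }
            )
            fit = ols("y ~ C(g1) + C(g2) + C(g1):C(g2)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=1)
            p_ref = tab.loc["C(g1):C(g2)", "PR(>F)"]
            assert row["p"] == pytest.approx(p_ref, rel=1e-6)

    def test_balanced_toy_table_matches_anova_to_high_precision(self):
        # fully balanced 3x3 design, exact sequential ANOVA equivalence
        rng = np.random.default_rng(50)
        g1 = np.repeat([0, 1, 2], 90)
        g2 = np.tile(np.repeat([0, 1, 2], 30), 3)
        y = 0.2 * g1 - 0.1 * g2 + 0.3 * (g1 == 1) * (g2 == 2) + rng.normal(0, 1, 270)
        out = pair_interaction_pvalues(y, np.column_stack([g1, g2]), np.array([[0, 1]]))
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y, "g1": pd.Categorical(g1), "g2": pd.Categorical(g2)})
        tab = sm.stats.anova_lm(
            ols("y ~ C(g1) + C(g2) + C(g1):C(g2)", data=df).fit(), typ=1
        )
        assert out["p"].iloc[0] == pytest.approx(tab.loc["C(g1):C(g2)", "PR(>F)"],
                                                 abs=1e-10)
        assert out["df1"].iloc[0] == 4

    def test_planted_interactions_detected_and_consolidated(self, nonadditive_study):
        panel, _, res = nonadditive_study
        r = pairwise_scan(res, panel, n_perm=150, pairs_per_perm=3000, seed=51)
        cons = r.consolidated
        found = set(map(tuple, cons[["marker_i", "marker_j"]].to_numpy()))
        assert (20, 55) in found
        assert (70, 100) in found

    def test_shuffled_residuals_destroy_interactions(self, nonadditive_study):
        panel, _, res = nonadditive_study
        rng = np.random.default_rng(52)
        shuffled = dm.ResidualPhenotype(
            res.residuals.copy(), res.midparent, res.mask
        )
        vals = shuffled.residuals[shuffled.mask]
        rng.shuffle(vals)
        shuffled.residuals[shuffled.mask] = vals
        r = pairwise_scan(shuffled, panel, threshold=1e-7, n_perm=0)
        assert len(r.significant) == 0

    def test_min_cell_precondition(self, nonadditive_study):
        panel, _, res = nonadditive_study
        y = res.values
        G = panel.genotypes[res.mask]
        out = pair_interaction_pvalues(y, G, np.array([[20, 55]]), min_cell=10**9)
        assert np.isnan(out["p"].iloc[0])


@pytest.fixture(scope="module")
def hub_study(small_panel):
    mmap = small_panel.mmap
    hub = 30
    partners = []
    for c in (1, 2, 8):  # distinct chromosomes, away from the hub's
        idx = mmap.chrom_indices(c)
        partners.append(int(idx[len(idx) // 2]))
    arch = dm.TraitArchitecture(
        interactions=[dm.Interaction(hub, p, aa=0.08) for p in partners],
        noise_sd=0.05,
    )
    y = dm.simulate_phenotypes(small_panel, arch, seed=53)
    return small_panel, midparent_residuals(y, small_panel), hub, partners


class TestHubForwardScan:
    def test_all_planted_partners_recovered(self, hub_study):
        panel, res, hub, partners = hub_study
        det = hub_forward_scan(res, panel, hub, threshold=1e-6)
        got = set(det["partner"])
        for p in partners:
            chrom = panel.mmap.chrom[p]
            same_chrom = [q for q in got if panel.mmap.chrom[q] == chrom]
            assert same_chrom, f"partner on chromosome {chrom} missed"
        assert det["round"].max() <= 3

    def test_null_hub_yields_no_partners(self, small_panel):
        rng = np.random.default_rng(54)
        y = rng.normal(0, 1, small_panel.n_diploids)
        res = midparent_residuals(y, small_panel)
        det = hub_forward_scan(res, small_panel, 30, threshold=1e-7)
        assert len(det) == 0

    def test_pairs_near_hub_removed_by_50kb_rule(self, small_panel):
        mmap = small_panel.mmap
        hub = 30
        close = pd.DataFrame(
            {
                "marker_i": [30, 99],
                "marker_j": [99, 30],
                "chrom_i": [mmap.chrom[30], mmap.chrom[99]],
                "bp_i": [mmap.bp[30] + 40_000, mmap.bp[99]],
                "chrom_j": [mmap.chrom[99], mmap.chrom[30]],
                "bp_j": [mmap.bp[99], mmap.bp[30] - 40_000],
                "p": [1e-9, 1e-9],
            }
        )
        out = remove_pairs_near_hub(close, hub, mmap, window_bp=50_000)
        assert len(out) == 0

    def test_hub_definition_threshold(self):
        cons = pd.DataFrame(
            {
                "marker_i": [5] * 21 + [9],
                "marker_j": list(range(100, 121)) + [200],
            }
        )
        hubs = find_hubs(cons, min_interactions=20)
        assert hubs["marker"].tolist() == [5]


class TestThreewayScan:
    def test_balanced_trio_matches_three_way_anova(self):
        rng = np.random.default_rng(55)
        levels = np.array(np.meshgrid([0, 1, 2], [0, 1, 2], [0, 1, 2])).reshape(3, -1).T
        G = np.repeat(levels, 15, axis=0)
        y = rng.normal(0, 1, G.shape[0]) + 0.5 * (
            (G[:, 0] == 1) & (G[:, 1] == 1) & (G[:, 2] == 1)
        )
        out = trio_interaction_pvalues(y, G, np.array([[0, 1, 2]]))
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame(
            {"y": y, "a": pd.Categorical(G[:, 0]), "b": pd.Categorical(G[:, 1]),
             "c": pd.Categorical(G[:, 2])}
        )
        tab = sm.stats.anova_lm(
            ols("y ~ (C(a) + C(b) + C(c)) ** 3", data=df).fit(), typ=1
        )
        assert out["p"].iloc[0] == pytest.approx(
            tab.loc["C(a):C(b):C(c)", "PR(>F)"], abs=1e-10
        )
        assert out["df1"].iloc[0] == 8

    def test_planted_three_way_effect_detected(self, small_panel):
        thinned = dm.thin_markers(small_panel.mmap, 5.0)
        trio = thinned[[2, 10, 20]]
        y = 0.4 * np.all(small_panel.genotypes[:, trio] == 1, axis=1).astype(float)
        rng = np.random.default_rng(56)
        y = y + rng.normal(0, 0.05, y.size)
        res = midparent_residuals(y, small_panel)
        r = threeway_scan(res, small_panel, threshold=1e-6, n_perm=0)
        sig = r.significant
        assert ((sig["marker_i"] == trio[0]) & (sig["marker_j"] == trio[1])
                & (sig["marker_k"] == trio[2])).any()

    def test_pairwise_only_data_controls_three_way_error(self, small_panel):
        rng = np.random.default_rng(57)
        arch = dm.TraitArchitecture(
            interactions=[dm.Interaction(20, 55, aa=0.08, dd=0.05)], noise_sd=0.05
        )
        y = dm.simulate_phenotypes(small_panel, arch, seed=58)
        res = midparent_residuals(y, small_panel)
        r = threeway_scan(res, small_panel, n_perm=60, trios_per_perm=300, seed=59)
        # detections at the permutation threshold stay near the nominal rate
        frac = (r.pairs["p"] < r.threshold).mean()
        assert frac < 0.05


class TestResolveHub:
    def _fam(self, rows):
        return pd.DataFrame(
            rows, columns=["family", "chrom", "bp", "neglog10p", "ci_left", "ci_right"]
        )

    def test_tightest_overlap_rule(self):
        det = self._fam(
            [
                [0, 3, 30_000, 12.0, 10_000, 50_000],
                [1, 3, 32_000, 9.0, 20_000, 40_000],
                [2, 3, 28_000, 7.0, 15_000, 60_000],
            ]
        )
        out = resolve_hub(det, hub_chrom=3, hub_interval=(25_000, 35_000))
        assert out["peak_bp"] == 30_000
        assert (out["left"], out["right"]) == (20_000, 40_000)
        assert not out["flagged"]

    def test_single_family_interval_is_the_bound(self):
        det = self._fam([[0, 3, 30_000, 12.0, 10_000, 50_000]])
        out = resolve_hub(det, 3, (25_000, 35_000))
        assert (out["left"], out["right"]) == (10_000, 50_000)

    def test_no_overlap_keeps_scan_interval_flagged(self):
        det = self._fam([[0, 5, 30_000, 12.0, 10_000, 50_000]])
        out = resolve_hub(det, 3, (25_000, 35_000))
        assert out["flagged"] and out["n_support"] == 0
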