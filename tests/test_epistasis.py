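"""Epistasis partitioning, hub modifiers, background profiles, MAT split."""

import numpy as np
import pandas as pd
import pytest

import diplomap as dm
from diplomap.epistasis import (
    EpistasisPartition,
    background_effect_profile,
    hub_modifier_magnitudes,
    mat_parent_of_origin_split,
    partition_interaction,
)
from diplomap.panels import DiploidPanel
from diplomap.markers import MarkerMap


def balanced_two_locus_panel(reps=60):
    """Fully crossed, balanced 3x3 design over two unlinked markers."""
    mmap = MarkerMap(np.array([1, 2]), np.array([100, 100]), np.array([1.0, 1.0]))
    cells = np.array(np.meshgrid([0, 1, 2], [0, 1, 2])).reshape(2, -1).T
    G = np.repeat(cells, reps, axis=0).astype(np.int8)
    n = G.shape[0]
    return DiploidPanel(
        mmap, G, np.zeros(n, int), np.zeros(n, int), np.zeros(n, np.int8), 0
    )


def planted_mixture(panel, aa, da, ad, dd, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    x1 = panel.genotypes[:, 0].astype(float) - 1
    x2 = panel.genotypes[:, 1].astype(float) - 1
    h1 = (panel.genotypes[:, 0] == 1).astype(float)
    h2 = (panel.genotypes[:, 1] == 1).astype(float)
    y = aa * x1 * x2 + da * h1 * x2 + ad * x1 * h2 + dd * h1 * h2
    return y + rng.normal(0, noise, y.size)


class TestPartitionInteraction:
    def test_pure_additive_by_additive(self):
        panel = balanced_two_locus_panel()
        y = planted_mixture(panel, aa=0.3, da=0, ad=0, dd=0, noise=0.0)
        p = partition_interaction(y, panel, 0, 1)
        assert p.pve["aa"] > 0
        assert p.pve["da"] < 1e-12 and p.pve["ad"] < 1e-12 and p.pve["dd"] < 1e-12
        assert p.frac_dominance_1 == pytest.approx(0.0, abs=1e-9)
        assert p.frac_dominance_2 == pytest.approx(0.0, abs=1e-9)

    def test_pure_dominance_by_dominance(self):
        panel = balanced_two_locus_panel()
        y = planted_mixture(panel, 0, 0, 0, dd=0.4, noise=0.0)
        p = partition_interaction(y, panel, 0, 1)
        assert p.frac_dominance_1 == pytest.approx(1.0, abs=1e-9)
        assert p.frac_dominance_2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_interaction_flagged(self):
        panel = balanced_two_locus_panel()
        rng = np.random.default_rng(1)
        x1 = panel.genotypes[:, 0].astype(float) - 1
        y = 0.3 * x1  # main effect only, no interaction
        p = partition_interaction(y, panel, 0, 1)
        assert p.flagged
        assert np.isnan(p.frac_dominance_1)

    def test_components_sum_to_saturated_interaction_ss(self):
        """The four sequential terms span the full 4-df interaction space."""
        panel = balanced_two_locus_panel()
        y = planted_mixture(panel, 0.2, -0.1, 0.15, 0.3, noise=0.3, seed=2)
        p = partition_interaction(y, panel, 0, 1)
        # oracle: interaction SS from the saturated 9-cell model
        g1, g2 = panel.genotypes[:, 0], panel.genotypes[:, 1]
        code = g1 * 3 + g2
        cell_means = np.array([y[code == c].mean() for c in range(9)])
        rss_full = np.sum((y - cell_means[code]) ** 2)
        # additive (main-effects) model residual
        X = np.column_stack(
            [np.ones(y.size), g1 == 1, g1 == 2, g2 == 1, g2 == 2]
        ).astype(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_add = np.sum((y - X @ beta) ** 2)
        ss_total = np.sum((y - y.mean()) ** 2)
        assert sum(p.pve.values()) == pytest.approx(
            (rss_add - rss_full) / ss_total, abs=1e-10
        )

    def test_planted_simplex_mixtures_recovered(self):
        """PVE shares track planted component shares on balanced designs."""
        panel = balanced_two_locus_panel(reps=5556)  # n ~ 50,000
        rng = np.random.default_rng(3)
        for trial in range(20):
            w = rng.dirichlet(np.ones(4))
            # interaction-space contrasts: centering the dominance indicator
            # removes the main-effect component of the raw h*x products, so
            # each code contributes variance only to its own interaction term
            x1 = panel.genotypes[:, 0].astype(float) - 1
            x2 = panel.genotypes[:, 1].astype(float) - 1
            h1 = (panel.genotypes[:, 0] == 1).astype(float)
            h1 -= h1.mean()
            h2 = (panel.genotypes[:, 1] == 1).astype(float)
            h2 -= h2.mean()
            codes = [x1 * x2, h1 * x2, x1 * h2, h1 * h2]
            codes = [(c - c.mean()) / c.std() for c in codes]
            y = sum(np.sqrt(wk) * c for wk, c in zip(w, codes))
            y = y + rng.normal(0, 1.0, y.size)
            p = partition_interaction(y, panel, 0, 1)
            total = sum(p.pve.values())
            shares = np.array([p.pve[t] for t in ("aa", "da", "ad", "dd")]) / total
            assert np.allclose(shares, w, atol=0.05)

    def test_directional_fractions_bounded(self):
        panel = balanced_two_locus_panel()
        y = planted_mixture(panel, 0.1, 0.2, -0.15, 0.05, noise=0.1, seed=4)
        p = partition_interaction(y, panel, 0, 1)
        assert 0.0 <= p.frac_dominance_1 <= 1.0
        assert 0.0 <= p.frac_dominance_2 <= 1.0


class TestHubModifiers:
    def _partition(self, hub, mod, aa=0.0, da=0.0, ad=0.0, dd=0.0):
        return EpistasisPartition(
            hub, mod, {"aa": aa, "da": da, "ad": ad, "dd": dd}, 0.0, 0.0, 1.0
        )

    def test_iqr_outlier_rule(self):
        parts = [self._partition(0, m, aa=1.0) for m in range(1, 5)]
        parts.append(self._partition(0, 5, aa=10.0))
        prof = hub_modifier_magnitudes(parts, hub=0)
        assert prof.table.loc[prof.table["modifier"] == 5, "major_additive"].item()
        assert prof.table["major_additive"].sum() == 1

    def test_equal_magnitudes_give_no_outliers(self):
        parts = [self._partition(0, m, aa=1.0, da=1.0) for m in range(1, 8)]
        prof = hub_modifier_magnitudes(parts, hub=0)
        assert not prof.table["major_additive"].any()
        assert not prof.table["major_dominance"].any()

    def test_channels_are_separate(self):
        parts = [self._partition(0, m, aa=0.1, da=0.1) for m in range(1, 7)]
        parts.append(self._partition(0, 7, aa=2.0))  # additive-channel outlier
        parts.append(self._partition(0, 8, da=2.0))  # dominance-channel outlier
        prof = hub_modifier_magnitudes(parts, hub=0)
        t = prof.table.set_index("modifier")
        assert t.loc[7, "major_additive"] and not t.loc[7, "major_dominance"]
        assert t.loc[8, "major_dominance"] and not t.loc[8, "major_additive"]

    def test_add_mod_sums_hub_additive_terms(self):
        parts = [self._partition(0, m, aa=0.2, ad=0.3, da=0.1, dd=0.05)
                 for m in range(1, 6)]
        prof = hub_modifier_magnitudes(parts, hub=0)
        assert np.allclose(prof.table["add_mod"], 0.5)
        assert np.allclose(prof.table["dom_mod"], 0.15)

    def test_wrong_orientation_errors(self):
        parts = [self._partition(1, 0, aa=0.2)]
        with pytest.raises(ValueError):
            hub_modifier_magnitudes(parts, hub=0)


class TestBackgroundProfile:
    def test_no_epistasis_gives_homogeneous_classes(self, small_panel):
        rng = np.random.default_rng(5)
        arch = dm.TraitArchitecture(additive={30: 0.5}, noise_sd=0.05)
        y = dm.simulate_phenotypes(small_panel, arch, seed=6)
        prof = background_effect_profile(
            y, small_panel, hub=30, modifiers=[5, 50, 80, 110], n_boot=200,
            min_class=15, seed=7,
        )
        t = prof.table[~prof.table["missing"]]
        assert len(t) > 10
        # class effects are homogeneous: CIs mostly cover the overall effect
        # (2a = 1.0; percentile bootstrap undercovers slightly at these n)
        assert ((t["a_lo"] <= 1.0) & (1.0 <= t["a_hi"])).mean() > 0.75
        assert t["a_effect"].mean() == pytest.approx(1.0, abs=0.05)

    def test_modifier_scaled_hub_effect_ordered_by_dosage(self, small_panel):
        mod = 50
        x_mod = small_panel.genotypes[:, mod].astype(float)
        x_hub = small_panel.genotypes[:, 30].astype(float) - 1
        rng = np.random.default_rng(8)
        y = (0.2 * x_mod) * x_hub + rng.normal(0, 0.05, x_hub.size)
        prof = background_effect_profile(
            y, small_panel, hub=30, modifiers=[mod, 5, 80, 110], n_boot=200,
            min_class=15, seed=9,
        )
        t = prof.table[~prof.table["missing"]].copy()
        t["mod_dosage"] = t["genotype"].str[0].astype(int)
        means = t.groupby("mod_dosage")["a_effect"].mean()
        assert means[0] < means[1] < means[2]

    def test_small_classes_reported_missing(self, small_panel):
        y = np.zeros(small_panel.n_diploids)
        prof = background_effect_profile(
            y, small_panel, hub=30, modifiers=[5, 50, 80, 110],
            min_class=10**6, n_boot=10, seed=10,
        )
        assert prof.table["missing"].all()
        assert prof.table["a_effect"].isna().all()

    def test_hub_among_modifiers_errors(self, small_panel):
        with pytest.raises(ValueError):
            background_effect_profile(
                np.zeros(small_panel.n_diploids), small_panel, hub=30,
                modifiers=[30, 5, 50, 80],
            )


class TestMatParentOfOriginSplit:
    def test_planted_origin_specific_dominance(self, small_panel):
        focal = 40
        arch = dm.TraitArchitecture(
            additive={focal: 0.05},
            dominance={focal: 0.3},
            mat_dominance_multiplier={focal: {2: 0.0, 3: 1.0}},
            noise_sd=0.02,
        )
        y = dm.simulate_phenotypes(small_panel, arch, seed=11)
        out = mat_parent_of_origin_split(y, small_panel, focal).set_index("mat_class")
        assert out.loc["3Sa/BYalpha", "dominance"] == pytest.approx(0.3, abs=0.05)
        assert out.loc["BYa/3Salpha", "dominance"] == pytest.approx(0.0, abs=0.05)

    def test_no_modifier_gives_equal_dominance_across_classes(self, small_panel):
        focal = 40
        arch = dm.TraitArchitecture(
            additive={focal: 0.05}, dominance={focal: 0.2}, noise_sd=0.02
        )
        y = dm.simulate_phenotypes(small_panel, arch, seed=12)
        out = mat_parent_of_origin_split(y, small_panel, focal)
        d = out["dominance"].to_numpy()
        assert np.all(np.abs(d - 0.2) < 0.05)
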