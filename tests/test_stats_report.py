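import numpy as np
import pandas as pd
import pytest

import holotherm as ht
from holotherm.synthetic_data import NoiseConfig, paper_default_config
from dataclasses import replace


class TestAssumptionChecks:
    def test_normal_groups_routed_parametric(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(size=30) for g in "ab"}
        out = ht.assumption_checks(groups)
        assert out["route"] == "parametric"
        assert all(v == "pass" for v in out["normality"].values())

    def test_heavy_tails_routed_nonparametric(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.standard_cauchy(60), "b": rng.standard_cauchy(60)}
        out = ht.assumption_checks(groups)
        assert out["route"] == "nonparametric"

    def test_small_group_insufficient(self):
        out = ht.assumption_checks({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert out["normality"]["a"] == "insufficient"
        assert out["route"] == "nonparametric"

    def test_constant_group_flagged(self):
        out = ht.assumption_checks({"a": [2.0, 2.0, 2.0],
                                    "b": [1.0, 2.0, 3.0]})
        assert out["normality"]["a"] == "constant"
        assert out["homogeneity"] == "undefined"

    def test_nominal_pass_rate(self):
        """Shapiro on standard-normal draws passes ≈ 95 % of the time."""
        rng = np.random.default_rng(42)
        passes = 0
        n = 200
        for _ in range(n):
            out = ht.assumption_checks({"g": rng.normal(size=30)})
            passes += out["normality"]["g"] == "pass"
        assert 0.90 <= passes / n <= 0.99


class TestOmnibus:
    def test_identical_groups_not_significant(self):
        tbl = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                            "g": ["a"] * 3 + ["b"] * 3})
        cmp_ = ht.omnibus_and_posthoc(tbl, "v", ["g"], force_parametric=True)
        assert cmp_.p_value > 0.9
        assert not cmp_.significant and cmp_.posthoc is None

    def test_single_level_factor_raises(self):
        tbl = pd.DataFrame({"v": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            ht.omnibus_and_posthoc(tbl, "v", ["g"])

    def test_posthoc_only_after_significant_omnibus(self):
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame({
            "v": np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                                 rng.normal(5, 1, 20)]),
            "g": ["a"] * 20 + ["b"] * 20 + ["c"] * 20})
        cmp_ = ht.omnibus_and_posthoc(tbl, "v", ["g"], force_parametric=True)
        assert cmp_.significant and cmp_.posthoc is not None
        assert len(cmp_.posthoc) == 3  # all pairwise contrasts

    def test_three_way_empty_cell_raises(self):
        tbl = pd.DataFrame({
            "v": np.arange(6, dtype=float),
            "a": ["x", "x", "x", "y", "y", "y"],
            "b": ["p", "p", "q", "p", "p", "q"],
            "c": ["u", "v", "u", "v", "u", "u"]})
        with pytest.raises(ValueError, match="cell"):
            ht.omnibus_and_posthoc(tbl, "v", ["a", "b", "c"])

    def test_paper_default_day14_contrasts(self, paper_assay, paper_meta):
        """Heated-vs-control day-14 density differs in PdC, not PdD."""
        dens = ht.areal_density(paper_assay.counts).merge(
            paper_meta[["holobiont", "arm"]], on="fragment_id")
        d14 = dens[dens["day"] == 14].copy()
        d14["logd"] = np.log10(d14["density"])
        pdc = ht.omnibus_and_posthoc(d14[d14["holobiont"] == "PdC"],
                                     "logd", ["arm"], force_parametric=True)
        pdd = ht.omnibus_and_posthoc(d14[d14["holobiont"] == "PdD"],
                                     "logd", ["arm"], force_parametric=True)
        assert pdc.significant
        assert not pdd.significant


class TestMixedEffects:
    def _density_table(self, noise):
        cfg = replace(paper_default_config(5), noise=noise)
        assay = ht.generate(cfg)
        from holotherm.experiment_core import design_with_arm
        dens = ht.areal_density(assay.counts).merge(
            design_with_arm(assay.design), on="fragment_id")
        dens["log_density"] = np.log10(dens["density"])
        return dens

    def test_zero_tank_variance_recovered(self):
        dens = self._density_table(NoiseConfig(tank_sd=0.0, colony_sd=0.0))
        out = ht.mixed_effects_screen(dens, "log_density",
                                      fixed=["arm", "day", "holobiont"],
                                      random=["tank", "colony"])
        assert out["variance_shares"]["tank"] < 0.05
        assert out["random_verdicts"]["tank"] == "negligible"

    def test_injected_colony_effect_dominant(self):
        """A large colony effect shows up as the dominant variance share."""
        dens = self._density_table(NoiseConfig(tank_sd=0.0, colony_sd=0.8))
        out = ht.mixed_effects_screen(dens, "log_density",
                                      fixed=["arm", "day", "holobiont"],
                                      random=["tank", "colony"])
        assert out["variance_shares"]["colony"] > out["variance_shares"]["tank"]
        assert out["variance_shares"]["colony"] > 0.3

    def test_single_level_random_factor_raises(self):
        tbl = pd.DataFrame({"v": [1.0, 2.0, 3.0], "t": [1, 1, 1],
                            "f": ["a", "b", "a"]})
        with pytest.raises(ValueError, match="random factor"):
            ht.mixed_effects_screen(tbl, "v", fixed=["f"], random=["t"])


class TestReport:
    def test_full_report_completeness(self, paper_assay):
        rep = ht.build_report(paper_assay)
        assert "pca" not in rep.gaps
        assert set(rep.pca_loadings.index) >= {
            "fv_fm", "df_fm_prime", "density", "calcification",
            "carbon_fixation", "carbon_translocation", "log10_dc"}
        assert rep.pca_scores.shape[1] == 2
        # every flagged significance has an associated test record
        for c in rep.comparisons:
            assert 0 <= c.p_value <= 1

    def test_missing_stage_flagged_as_gap(self, paper_assay):
        from holotherm.experiment_core import empty_table
        partial = ht.AssaySet(
            design=paper_assay.design, pam=empty_table("pam"),
            weights=paper_assay.weights, counts=paper_assay.counts,
            census=paper_assay.census, qpcr=paper_assay.qpcr,
            isotopes=paper_assay.isotopes, clones=paper_assay.clones,
            metadata=paper_assay.metadata)
        rep = ht.build_report(partial)
        assert "photochemistry" in rep.gaps

    def test_null_arms_pca_separates_holobionts(self):
        """With identical arms, the leading PC separates PdC from PdD
        (the generator's between-group structure), not the arms."""
        from holotherm.synthetic_data import null_effect_config
        rep = ht.build_report(ht.generate(null_effect_config(3)))
        scores = rep.pca_scores.reset_index()
        hb = scores["holobiont"]
        pc1 = scores["PC1"]
        between_hb = abs(pc1[hb == "PdC"].mean() - pc1[hb == "PdD"].mean())
        arm = scores["arm"]
        between_arm = abs(pc1[arm == "control"].mean() - pc1[arm == "heat"].mean())
        assert between_hb > 3 * between_arm
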