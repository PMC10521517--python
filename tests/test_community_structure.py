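import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import holotherm as ht
from holotherm.community_structure import OrdinationResult


def _qpcr(ct_c, ct_d, fid="f", day=0):
    rows = [(fid, day, "C", r, ct_c) for r in (1, 2, 3)]
    rows += [(fid, day, "D", r, ct_d) for r in (1, 2, 3)]
    return pd.DataFrame(rows, columns=["fragment_id", "day", "primer",
                                       "replicate", "ct"])


class TestDCRatio:
    @pytest.mark.parametrize("ct_c,ct_d,expected", [
        (20.0, 30.0, 2.0 ** -10),   # 9.765625e-4
        (25.0, 25.0, 1.0),
        (30.0, 20.0, 1024.0),
    ])
    def test_delta_ct_model(self, ct_c, ct_d, expected):
        out = ht.dc_ratio(_qpcr(ct_c, ct_d))
        assert out["dc"].iloc[0] == pytest.approx(expected)
        assert not out["censored"].iloc[0]

    def test_replicate_mean_of_detected(self):
        q = _qpcr(20.0, 30.0)
        q.loc[q["primer"] == "D", "ct"] = [29.0, 30.0, 31.0]
        out = ht.dc_ratio(q)
        assert out["dc"].iloc[0] == pytest.approx(2.0 ** -10)

    def test_nondetect_primer_censored_at_limit(self):
        q = _qpcr(20.0, np.nan)
        out = ht.dc_ratio(q, ct_limit=40.0)
        assert out["dc"].iloc[0] == pytest.approx(2.0 ** -20)
        assert bool(out["censored"].iloc[0])

    def test_both_nondetect_skipped(self, caplog):
        q = _qpcr(np.nan, np.nan)
        with caplog.at_level("WARNING"):
            out = ht.dc_ratio(q)
        assert out.empty

    def test_log10_consistency(self):
        """log10 D/C = −ΔCT·log10(2); doubling ΔCT doubles its magnitude."""
        one = ht.dc_ratio(_qpcr(20.0, 25.0))["log10_dc"].iloc[0]
        two = ht.dc_ratio(_qpcr(20.0, 30.0))["log10_dc"].iloc[0]
        assert one == pytest.approx(-5 * np.log10(2))
        assert two == pytest.approx(2 * one)


class TestShufflingIndex:
    @pytest.mark.parametrize("dc,expected", [
        (0.0, -1.0),       # complete Cladocopium dominance
        (1.0, 0.0),        # even community
    ])
    def test_endpoints(self, dc, expected):
        assert ht.shuffling_index(dc) == pytest.approx(expected)

    def test_durusdinium_dominance_limit(self):
        assert ht.shuffling_index(1e12) > 1 - 1e-11

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            ht.shuffling_index(-0.1)

    _dc = st.one_of(st.just(0.0), st.floats(1e-9, 1e12))

    @given(_dc, _dc)
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, a, b):
        ia, ib = ht.shuffling_index(a), ht.shuffling_index(b)
        assert -1.0 <= ia <= 1.0
        if a < b:
            assert ia < ib
        assert (ia == -1.0) == (a == 0.0)


class TestTrajectory:
    def _design(self, n=4):
        return pd.DataFrame(
            [(f"f{i}", "PdC", 1, 4, 32.0) for i in range(n)],
            columns=["fragment_id", "holobiont", "colony", "tank",
                     "temperature"])

    def test_constant_ratio_slope_zero(self):
        ratios = pd.DataFrame({
            "fragment_id": ["f0", "f1", "f2", "f3"],
            "day": [0, 0, 14, 14], "dc": 1e-6, "log10_dc": -6.0,
            "censored": False})
        out = ht.dc_trajectory(ratios, self._design())
        assert out["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_time_point_raises(self):
        ratios = pd.DataFrame({"fragment_id": ["f0", "f1"], "day": 0,
                               "dc": 1e-6, "log10_dc": -6.0, "censored": False})
        with pytest.raises(ValueError, match="time points"):
            ht.dc_trajectory(ratios, self._design(2))

    def test_paper_default_trajectories(self, paper_assay):
        """Heated PdC climbs ≈ 3 log₁₀ units; control PdD declines
        significantly; control PdC drift is not significant."""
        ratios = ht.dc_ratio(paper_assay.qpcr)
        out = ht.dc_trajectory(ratios, paper_assay.design).set_index(
            ["holobiont", "arm"])
        assert out.loc[("PdC", "heat"), "log10_change"] == pytest.approx(3.0, abs=0.5)
        assert out.loc[("PdD", "control"), "slope"] < 0
        assert out.loc[("PdD", "control"), "p_value"] < 0.05
        assert out.loc[("PdC", "control"), "p_value"] > 0.05


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[5, 3], [5, 3]], columns=["C42", "C1"])
        d = ht.zero_adjusted_bray_curtis(m)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_two_empty_samples_zero(self):
        """The dummy species prevents 0/0 for all-zero samples."""
        m = pd.DataFrame([[0, 0], [0, 0]], columns=["C42", "C1"])
        d = ht.zero_adjusted_bray_curtis(m)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_hand_summed(self):
        """[10,0] vs [0,10] with the dummy → 20/22 ≈ 0.9091."""
        m = pd.DataFrame([[10, 0], [0, 10]], columns=["a", "b"])
        d = ht.zero_adjusted_bray_curtis(m)
        assert d.iloc[0, 1] == pytest.approx(20 / 22)

    def test_negative_counts_rejected(self):
        m = pd.DataFrame([[1, -2], [0, 1]])
        with pytest.raises(ValueError):
            ht.zero_adjusted_bray_curtis(m)

    @given(st.lists(st.lists(st.integers(0, 50), min_size=3, max_size=3),
                    min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_matrix_properties(self, rows):
        d = ht.zero_adjusted_bray_curtis(pd.DataFrame(rows)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d < 1).all()  # dummy bounds below 1


class TestNMDS:
    def test_equilateral_configuration(self):
        d = pd.DataFrame(0.5 * (1 - np.eye(3)))
        res = ht.nmds(d, restarts=8, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-3)
        xy = res.coordinates.to_numpy()
        pd_ = np.linalg.norm(xy[0] - xy[1]), np.linalg.norm(xy[1] - xy[2])
        assert pd_[0] == pytest.approx(pd_[1], rel=0.05)

    def test_rank_preserving_recovery(self):
        """Distances of a planar configuration embed with near-zero stress."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = ht.nmds(pd.DataFrame(d), restarts=10, seed=3)
        assert res.stress < 0.02

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        a = ht.nmds(d, restarts=5, seed=11)
        b = ht.nmds(d, restarts=5, seed=11)
        assert np.array_equal(a.coordinates.to_numpy(),
                              b.coordinates.to_numpy())
        assert a.stress == b.stress

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ht.nmds(d)


class TestCompleteLinkage:
    def test_all_zero_one_group(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        labels = ht.complete_linkage_groups(d, 90.0)
        assert labels.nunique() == 1

    def test_two_blocks_at_cut(self):
        d = np.full((4, 4), 0.9)
        d[:2, :2] = 0.02
        d[2:, 2:] = 0.02
        np.fill_diagonal(d, 0.0)
        labels = ht.complete_linkage_groups(pd.DataFrame(d), 90.0)
        assert labels.nunique() == 2
        assert labels.iloc[0] == labels.iloc[1] != labels.iloc[2]

    def test_four_point_dendrogram_oracle(self):
        """d(1,2)=d(3,4)=0.05, others 0.5 → groups {1,2} and {3,4}
        (exhaustive dendrogram by hand: merges at 0.05, 0.05, 0.5)."""
        d = np.full((4, 4), 0.5)
        d[0, 1] = d[1, 0] = 0.05
        d[2, 3] = d[3, 2] = 0.05
        np.fill_diagonal(d, 0.0)
        labels = ht.complete_linkage_groups(pd.DataFrame(d), 90.0)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[0] != labels.iloc[2]

    def test_cut_domain(self):
        d = pd.DataFrame(np.zeros((2, 2)))
        for cut in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                ht.complete_linkage_groups(d, cut)


def test_genus_grouping_regardless_of_treatment(paper_assay):
    """Clone-library ordination groups samples by dominant genus at the
    90 %-similarity cut, not by temperature arm."""
    mat = ht.community_matrix(paper_assay.clones, level="metahaplotype",
                              relative=True)
    d = ht.zero_adjusted_bray_curtis(mat)
    labels = ht.complete_linkage_groups(d, 90.0)
    genus = pd.Series([s.split("-")[0] for s in mat.index], index=mat.index)
    # samples of the same genus always share a label
    for hb, grp in labels.groupby(genus):
        assert grp.nunique() == 1
    assert labels[genus == "PdC"].iloc[0] != labels[genus == "PdD"].iloc[0]


def test_microexample_dc(micro):
    out = ht.dc_ratio(micro.qpcr)
    assert out["dc"].iloc[0] == pytest.approx(2.0 ** -10)
    assert ht.shuffling_index(out["dc"].iloc[0]) == pytest.approx(
        2 * (2 ** -10) / (1 + 2 ** -10) - 1)
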