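"""Repeated-measures statistics and the cluster permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phaseconn as pc
from phaseconn.clusterstats import paired_t, rm_anova_f

from conftest import rm_anova_brute


class TestRMANOVA:
    def test_worked_three_by_three_table(self):
        f, df, degen = rm_anova_f(np.array([[1, 2, 2], [2, 1, 3], [3, 3, 4]],
                                           dtype=float))
        assert f == pytest.approx(3.0, abs=1e-12)
        assert df == (2, 4)
        assert not degen

    def test_agrees_with_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.normal(size=(5, 3))
            f, df, _ = rm_anova_f(table)
            f_ref, df_ref = rm_anova_brute(table)
            assert f == pytest.approx(f_ref, abs=1e-10)
            assert df == df_ref

    def test_agrees_with_pingouin(self, rng):
        """Cross-check against an established RM-ANOVA implementation."""
        import pandas as pd
        import pingouin as pg
        table = rng.normal(size=(8, 3))
        f, df, _ = rm_anova_f(table)
        long = pd.DataFrame({
            "y": table.ravel(),
            "subject": np.repeat(np.arange(8), 3),
            "cond": np.tile(np.arange(3), 8),
        })
        res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert f == pytest.approx(float(res["F"][0]), rel=1e-9)
        assert df == (int(res["ddof1"][0]), int(res["ddof2"][0]))

    def test_constant_conditions_give_zero_f(self):
        f, _, _ = rm_anova_f(np.array([[1.0, 1, 1], [2, 2, 2], [5, 5, 5]]))
        assert f == 0.0

    def test_df_at_twenty_subjects(self, rng):
        data = rng.normal(size=(20, 3, 2, 2, 1))
        res = pc.rm_anova_edges(data, ("a", "b"), ("theta",))
        assert res.df == (2, 38)

    def test_missing_cell_named(self):
        data = np.random.default_rng(0).normal(size=(3, 3, 2, 2, 1))
        data[1, 2] = np.nan
        with pytest.raises(ValueError, match="sub-02.*rep3"):
            pc.rm_anova_edges(data, ("a", "b"), ("theta",),
                              subjects=["sub-01", "sub-02", "sub-03"],
                              conditions=["rep1", "rep2", "rep3"])

    def test_zero_residual_variance_flags_infinite_f(self):
        # perfectly consistent condition effect across subjects
        base = np.array([[0.0, 1.0, 2.0]]) + np.arange(4)[:, None]
        f, _, degen = rm_anova_f(base)
        assert degen and np.isinf(f)


class TestPairedT:
    def test_worked_differences(self):
        t, df, _ = paired_t(np.array([1.0, 2.0, 3.0, 4.0])[:, None])
        assert t[0] == pytest.approx(3.872983, abs=1e-5)
        assert df == 3

    def test_alternating_differences_give_zero(self):
        t, _, _ = paired_t(np.array([1.0, -1.0, 1.0, -1.0])[:, None])
        assert t[0] == 0.0

    def test_constant_differences_flag_degenerate(self):
        t, _, degen = paired_t(np.full((5, 1), 2.0))
        assert degen[0] and np.isinf(t[0])

    def test_df_at_twenty_subjects(self, rng):
        data = rng.normal(size=(20, 3, 2, 2, 1))
        res = pc.paired_t_edges(data, 0, 2, ("a", "b"), ("theta",))
        assert res.df == (19,)

    def test_matches_scipy(self, rng):
        from scipy import stats
        a = rng.normal(size=(12,))
        b = rng.normal(size=(12,))
        t, df, _ = paired_t((b - a)[:, None])
        ref = stats.ttest_rel(b, a)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-12)


def _planted_dataset(rng, n_sub=10, n_ch=6, n_band=2, effect=1.0):
    """Band-WPLI-like tensor with one strong condition effect at edge
    (0, 1) in band 0."""
    data = rng.uniform(0.1, 0.3, size=(n_sub, 3, n_ch, n_ch, n_band))
    data = (data + data.transpose(0, 1, 3, 2, 4)) / 2
    bump = effect * np.array([0.0, 0.15, 0.3])[None, :]
    bump = bump + rng.normal(0, 0.01, size=(n_sub, 3))
    data[:, :, 0, 1, 0] += bump
    data[:, :, 1, 0, 0] += bump
    idx = np.arange(n_ch)
    data[:, :, idx, idx, :] = 0.0
    return data


class TestPermutationClusterTest:
    def test_planted_effect_recovered_and_reproducible(self, rng):
        data = _planted_dataset(rng)
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        scheme = pc.PermutationScheme(n_perm=1000, seed=11)
        out1 = pc.permutation_cluster_test(data, res, scheme)
        out2 = pc.permutation_cluster_test(data, res, scheme)
        sig = out1.significant_clusters(0.01)
        assert any((0, 1, 0) in c.edges for c in sig)
        assert [(c.edges, c.mass, c.p) for c in out1.clusters] == \
               [(c.edges, c.mass, c.p) for c in out2.clusters]

    def test_p_estimator_never_zero(self, rng):
        data = _planted_dataset(rng, effect=3.0)
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        scheme = pc.PermutationScheme(n_perm=500, seed=2)
        out = pc.permutation_cluster_test(data, res, scheme)
        assert all(c.p >= 1.0 / 501 for c in out.clusters)

    def test_exhaustive_mode_at_two_subjects(self, rng, caplog):
        data = _planted_dataset(rng, n_sub=2)
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        scheme = pc.PermutationScheme(n_perm=1000, seed=3)
        with caplog.at_level("WARNING"):
            out = pc.permutation_cluster_test(data, res, scheme)
        assert out.exhaustive
        assert out.n_perm == 36  # 6 label orders per subject, 2 subjects
        assert "exhaustively" in caplog.text

    def test_t_contrast_sign_flip_exhaustive(self, rng, caplog):
        data = _planted_dataset(rng, n_sub=8)
        res = pc.paired_t_edges(data, 0, 2, tuple("abcdef"), ("x", "y"))
        scheme = pc.PermutationScheme(n_perm=1000, seed=4)
        with caplog.at_level("WARNING"):
            out = pc.permutation_cluster_test(data, res, scheme,
                                              contrast=(0, 2))
        assert out.exhaustive and out.n_perm == 256
        sig = out.significant_clusters(0.05)
        assert any((0, 1, 0) in c.edges for c in sig)
        assert all(c.tail == "pos" for c in sig)

    def test_corrected_p_invariant_to_electrode_relabeling(self, rng):
        data = _planted_dataset(rng)
        perm = np.array([3, 0, 5, 1, 4, 2])
        data_p = data[:, :, perm][:, :, :, perm]
        scheme = pc.PermutationScheme(n_perm=800, seed=6)
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        res_p = pc.rm_anova_edges(data_p, tuple("abcdef"), ("x", "y"))
        out = pc.permutation_cluster_test(data, res, scheme)
        out_p = pc.permutation_cluster_test(data_p, res_p, scheme)
        assert sorted(c.p for c in out.clusters) == \
               sorted(c.p for c in out_p.clusters)

    def test_mask_restricts_cluster_formation(self, rng):
        data = _planted_dataset(rng)
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        mask = np.zeros((6, 6, 2), dtype=bool)  # mask out everything
        res.stat = pc.apply_cst_mask(res.stat, mask)
        out = pc.permutation_cluster_test(
            data, res, pc.PermutationScheme(n_perm=200, seed=7), mask)
        assert out.clusters == []

    def test_shared_electrode_adjacency_merges_edges(self):
        """Edges (0,1) and (1,2) share electrode 1 and join one cluster;
        an isolated strong edge (4,5) forms its own."""
        rng = np.random.default_rng(12)
        data = _planted_dataset(rng)
        bump = np.array([0.0, 0.15, 0.3])[None, :]
        for i, j in [(1, 2), (4, 5)]:
            data[:, :, i, j, 0] += bump
            data[:, :, j, i, 0] += bump
        res = pc.rm_anova_edges(data, tuple("abcdef"), ("x", "y"))
        out = pc.permutation_cluster_test(
            data, res, pc.PermutationScheme(n_perm=300, seed=8))
        clusters_with = lambda e: [c for c in out.clusters if e in c.edges]
        c01 = clusters_with((0, 1, 0))
        c12 = clusters_with((1, 2, 0))
        c45 = clusters_with((4, 5, 0))
        assert c01 and c12 and c45
        assert c01[0] is c12[0]
        assert c45[0] is not c01[0]
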