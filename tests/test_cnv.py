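"""Normalization, gene calling, QC, tumor content, scaling, variant filters."""

import numpy as np
import pandas as pd
import pytest

from mousecred import (CnrNormalizer, ReadCountMatrix, call_genes,
                       estimate_tumor_content, filter_variants,
                       gene_calls_frame, mapd, scale_cnr)
from mousecred.cnv import PipelineError, VariantRecord, qc_sample
from mousecred.simulate import (default_gc_bias, simulate_cn_profile,
                                simulate_read_counts)
from conftest import NORMAL_IDS, combine_counts


class TestNormalization:
    def test_sample_identical_to_pooled_normal_is_zero(self, toy_panel,
                                                       small_layout):
        """Self-ratio: a sample equal to the pooled normal has log2CNR == 0."""
        truth = simulate_cn_profile(small_layout)
        counts = simulate_read_counts(truth, toy_panel,
                                      NORMAL_IDS + ["probe"], noise=False)
        norm = CnrNormalizer().fit(counts, toy_panel, NORMAL_IDS)
        cnr = norm.transform(counts)["probe"]
        np.testing.assert_allclose(cnr.values, 0.0, atol=1e-9)

    def test_planted_doubling_recovered(self, toy_panel, small_layout):
        """A doubled small gene lands at log2CNR ~ 1; the compositional shift
        from its extra mass on the rest of the panel is bounded."""
        normal = simulate_cn_profile(small_layout)
        # g5_2 is 8 amplicons of 124: < 7% of panel mass
        gene_rows = toy_panel.df[toy_panel.df["target"] == "g5_2"]
        tumor = simulate_cn_profile(small_layout, events=[{
            "chrom": "5", "start": int(gene_rows["start"].min()),
            "end": int(gene_rows["end"].max()), "cn": 4}])
        counts = combine_counts(
            simulate_read_counts(normal, toy_panel, NORMAL_IDS, noise=False),
            simulate_read_counts(tumor, toy_panel, "t", noise=False))
        cnr = CnrNormalizer().fit(counts, toy_panel, NORMAL_IDS).transform(
            counts)["t"]
        ids = gene_rows["amplicon"]
        assert cnr.loc[ids].mean() == pytest.approx(1.0, abs=0.05)

    def test_gc_trend_removed(self, toy_panel, small_layout):
        """A synthetic linear GC trend leaves a near-zero residual slope."""
        truth = simulate_cn_profile(small_layout)
        counts = simulate_read_counts(truth, toy_panel, NORMAL_IDS + ["t"],
                                      noise=False)
        gc = toy_panel.df.set_index("amplicon")["gc"]
        skewed = counts.counts.copy().astype(float)
        skewed["t"] *= 2.0 ** (3.0 * (gc.values - gc.values.mean()))
        skewed_m = ReadCountMatrix(skewed, allow_float=True)
        norm = CnrNormalizer().fit(skewed_m, toy_panel, NORMAL_IDS)
        cnr = norm.transform(skewed_m)["t"]
        slope = np.polyfit(gc.loc[cnr.index].values, cnr.values, 1)[0]
        assert abs(slope) * 0.10 < 0.02  # |slope| per 10% GC

    def test_requires_two_normals(self, normal_counts, toy_panel):
        with pytest.raises(PipelineError, match="2 normal"):
            CnrNormalizer().fit(normal_counts, toy_panel, ["n0"])

    def test_bottom_percentile_dropped(self, toy_panel, small_layout):
        truth = simulate_cn_profile(small_layout)
        counts = simulate_read_counts(truth, toy_panel, NORMAL_IDS,
                                      noise=False)
        norm = CnrNormalizer(drop_percentile=5.0).fit(
            counts, toy_panel, NORMAL_IDS)
        assert len(norm.retained_amplicons_) <= np.ceil(0.96 * len(toy_panel))
        assert len(norm.retained_amplicons_) >= 0.94 * len(toy_panel)


class TestGeneCalls:
    def _null_sample(self, toy_panel, small_layout, seed):
        truth = simulate_cn_profile(small_layout)
        return simulate_read_counts(truth, toy_panel, "t", mean_depth=500,
                                    dispersion=0.02,
                                    gc_bias=default_gc_bias, seed=seed)

    def test_null_sample_mostly_neutral(self, toy_panel, small_layout,
                                        normal_counts, fitted_normalizer,
                                        normals_cnr):
        """Type-I control: a sample from the normal distribution yields >= 95%
        neutral gene states at q = 0.05."""
        states = []
        for seed in range(5):
            t = self._null_sample(toy_panel, small_layout, 300 + seed)
            cnr = fitted_normalizer.transform(t)["t"]
            calls = call_genes(cnr, normals_cnr, toy_panel)
            states.extend(c.state for c in calls)
        assert np.mean([s == 0 for s in states]) >= 0.95

    def test_z_arithmetic(self, toy_panel, normals_cnr):
        """A gene 1.0 above normals with SD 0.05 scores z = 20 and is called."""
        cnr = normals_cnr.mean(axis=1).copy()
        gene_ids = toy_panel.df.loc[toy_panel.df["target"] == "g3_1",
                                    "amplicon"]
        gene_ids = [g for g in gene_ids if g in cnr.index]
        # rebuild normals with known per-gene spread
        rng = np.random.default_rng(0)
        normals = pd.DataFrame(
            {f"n{i}": pd.Series(0.0, index=cnr.index) for i in range(4)})
        for i in range(4):
            normals.iloc[:, i] = rng.normal(0, 1e-6, size=len(cnr))
        for i, off in enumerate([-0.05, -0.017, 0.017, 0.05]):
            normals.loc[gene_ids, f"n{i}"] = off  # gene SD ~ 0.05
        sample = pd.Series(0.0, index=cnr.index)
        sample.loc[gene_ids] = 1.0
        calls = {c.gene: c for c in call_genes(sample, normals, toy_panel)}
        c = calls["g3_1"]
        sd = normals.loc[gene_ids].mean(axis=0).std(ddof=1)
        assert c.z == pytest.approx(1.0 / sd, rel=1e-6)
        assert c.q < 1e-10 and c.state == 1

    def test_noise_zeroing_rule(self, toy_panel, normals_cnr):
        """q > 0.05 AND |log2CNR| < 0.2 -> state zeroed (AND rule); the OR
        mode additionally zeroes small-but-significant calls."""
        rng = np.random.default_rng(1)
        normals = pd.DataFrame(
            {f"n{i}": pd.Series(rng.normal(0, 0.2, size=len(normals_cnr)),
                                index=normals_cnr.index) for i in range(4)})
        sample = pd.Series(0.15, index=normals_cnr.index)
        for c in call_genes(sample, normals, toy_panel, zero_rule="and"):
            if c.q > 0.05 and abs(c.log2cnr) < 0.2:
                assert c.state == 0

    def test_zero_sd_flagged(self, toy_panel, normals_cnr):
        normals = pd.DataFrame(
            {f"n{i}": pd.Series(0.0, index=normals_cnr.index)
             for i in range(4)})
        sample = pd.Series(0.5, index=normals_cnr.index)
        with pytest.warns(UserWarning, match="zero normal SD"):
            calls = call_genes(sample, normals, toy_panel)
        assert all(c.state == 0 and "normals-sd-zero" in c.flags
                   for c in calls)

    def test_bh_q_monotone_in_p(self, toy_panel, small_layout, normal_counts,
                                fitted_normalizer, normals_cnr):
        t = self._null_sample(toy_panel, small_layout, 77)
        cnr = fitted_normalizer.transform(t)["t"]
        df = gene_calls_frame(call_genes(cnr, normals_cnr, toy_panel))
        df = df.sort_values("p")
        assert (np.diff(df["q"].values) >= -1e-12).all()
        assert (df["q"] >= df["p"] - 1e-12).all()


class TestQc:
    def test_mapd_hand_examples(self, toy_panel):
        order = toy_panel.genomic_order()["amplicon"]
        alternating = pd.Series(
            [0.0 if i % 2 == 0 else 0.1 for i in range(len(order))],
            index=order.values)
        assert mapd(alternating, toy_panel) == pytest.approx(0.1)
        noisy = alternating * 6.0  # 0 / 0.6 alternation
        assert mapd(noisy, toy_panel) == pytest.approx(0.6)
        constant = pd.Series(0.3, index=order.values)
        assert mapd(constant, toy_panel) == 0.0

    def test_qc_pass_fail(self, normal_counts, toy_panel):
        order = toy_panel.genomic_order()["amplicon"]
        good = pd.Series(0.0, index=order.values)
        rep = qc_sample(normal_counts, good, toy_panel, "n0")
        assert rep.mapd_pass and rep.passed
        bad = pd.Series([0.0 if i % 2 == 0 else 0.6
                         for i in range(len(order))], index=order.values)
        rep2 = qc_sample(normal_counts, bad, toy_panel, "n0",
                         tumor_content=0.2)
        assert not rep2.mapd_pass and rep2.tumor_content_pass is False


class TestTumorContentAndScaling:
    @pytest.mark.parametrize("cnr_linear,expected_tc", [
        (1.0, 0.0), (0.6, 0.4), (0.3, 0.7),
    ])
    def test_tumor_content_from_flox(self, toy_panel, normals_cnr, cnr_linear,
                                     expected_tc):
        sample = pd.Series(0.0, index=normals_cnr.index)
        flox_ids = [a for a in toy_panel.df.loc[
            toy_panel.df["target"] == "Trp53_flox", "amplicon"]
            if a in sample.index]
        sample.loc[flox_ids] = np.log2(cnr_linear)
        est = estimate_tumor_content(sample, toy_panel, "Trp53_flox")
        assert est.tumor_content == pytest.approx(expected_tc)

    def test_missing_flox_target_errors(self, toy_panel, normals_cnr):
        with pytest.raises(PipelineError):
            estimate_tumor_content(pd.Series(0.0, index=normals_cnr.index),
                                   toy_panel, "Nf1_flox")

    def test_scale_cnr_examples(self):
        assert scale_cnr(pd.Series([0.0]), 1.0, 2.0)[0] == pytest.approx(2.0)
        # p=0.5, psi=2: CNR 1.25 inverts to CN 3
        cnr = pd.Series([np.log2(1.25)])
        assert scale_cnr(cnr, 0.5, 2.0)[0] == pytest.approx(3.0)
        assert scale_cnr(pd.Series([np.log2(1.2)]), 1.0, 2.0,
                         round_to_int=True)[0] == 2.0

    def test_scale_inverts_simulator_exactly(self, small_layout, toy_panel):
        """Zero-noise pipeline identity: planted integer CN is recovered."""
        truth = simulate_cn_profile(
            small_layout,
            events=[{"chrom": "4", "start": 0, "end": 50_000_000, "cn": 5}],
            purity=0.6, ploidy=2.0)
        cnr_linear = truth.expected_panel_cnr(toy_panel)
        cn = scale_cnr(np.log2(cnr_linear), purity=0.6, ploidy=2.0)
        on4 = toy_panel.df.set_index("amplicon")["chrom"] == "4"
        assert np.allclose(cn[on4.values], 5.0)
        assert np.allclose(cn[(~on4.values)
                              & ~cnr_linear.index.str.contains("flox")], 2.0)

    def test_negative_cn_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = scale_cnr(pd.Series([-5.0]), 0.9, 2.0)
        assert out[0] == 0.0


class TestVariantFilter:
    def _rec(self, **kw):
        base = dict(chrom="1", pos=100, ref="A", alt="T", depth=150,
                    alt_forward=10, alt_reverse=10, homopolymer_len=2,
                    allele_fraction=0.2)
        base.update(kw)
        return VariantRecord(**base)

    def test_all_rules_satisfied(self):
        (v,) = filter_variants([self._rec()])
        assert v.passed and not v.reasons

    @pytest.mark.parametrize("kw,reason", [
        (dict(depth=90, alt_forward=10, alt_reverse=10), "depth"),
        (dict(alt_forward=12, alt_reverse=1), "strand-ratio"),
        (dict(alt_forward=5, alt_reverse=5), "alt-reads"),
        (dict(homopolymer_len=4), "homopolymer"),
        (dict(allele_fraction=0.1), "allele-fraction"),
    ])
    def test_single_rule_failures(self, kw, reason):
        (v,) = filter_variants([self._rec(**kw)])
        assert not v.passed and reason in v.reasons

    def test_boundaries_follow_strict_inequalities(self):
        # depth must be > 100; exactly 100 fails
        (v,) = filter_variants([self._rec(depth=100)])
        assert "depth" in v.reasons
        # strand ratio bounds are inclusive: exactly 0.2 and 5.0 pass
        (v2,) = filter_variants([self._rec(alt_forward=50, alt_reverse=10,
                                           depth=200)])
        assert "strand-ratio" not in v2.reasons
        # all-forward reads give infinite ratio -> strand failure
        (v3,) = filter_variants([self._rec(alt_forward=20, alt_reverse=0)])
        assert "strand-ratio" in v3.reasons
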