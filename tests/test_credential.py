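"""Credentialing statistics: FGA, copy-state score, flox ratios, Fisher,
permutation tests, synteny mapping and scenarios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mousecred.credential import (CredentialError, arm_specificity_test,
                                  copy_state_score, expected_flox_log2cnr,
                                  fisher_exact_2x2, flox_ratio,
                                  fraction_genes_altered,
                                  genotype_ratio_regression, map_syntenic,
                                  recurrent_aneuploidy_permutation,
                                  synteny_scenario_test)
from mousecred.genome import mouse_layout
from mousecred.simulate import simulate_aneuploidy_matrix

MB = 1_000_000


def calls_frame(values, chrom="1", spacing=1000):
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(len(values))],
        "chrom": chrom, "start": np.arange(len(values)) * spacing,
        "end": np.arange(len(values)) * spacing + 100,
        "log2cnr": values, "state": np.sign(values).astype(int)})


class TestFga:
    def test_all_zero(self):
        out = fraction_genes_altered(calls_frame([0.0] * 10))
        assert out.fga == 0.0

    def test_exact_fraction(self):
        values = [0.5] * 48 + [0.0] * 71  # 48 of 119 altered
        out = fraction_genes_altered(calls_frame(values))
        assert out.fga == pytest.approx(48 / 119)
        assert out.n_genes == 119

    def test_boundary_is_strict(self):
        out = fraction_genes_altered(calls_frame([0.2, -0.2, 0.2001]))
        assert out.n_altered == 1

    def test_order_free(self):
        values = [0.5, -0.3, 0.0, 0.1]
        a = fraction_genes_altered(calls_frame(values))
        b = fraction_genes_altered(calls_frame(values[::-1]))
        assert a.fga == b.fga

    def test_empty_gene_set_errors(self):
        with pytest.raises(CredentialError):
            fraction_genes_altered(calls_frame([0.1]), gene_set=[])


class TestCopyStateScore:
    layout = mouse_layout({"1": 100 * MB})

    def _score(self, states, **kw):
        df = calls_frame([0.0] * len(states))
        df["state"] = states
        return copy_state_score(df, self.layout, **kw)

    def test_quiet_arm_scores_one(self):
        assert self._score([0, 0, 0, 0]).total == 1

    def test_three_runs(self):
        assert self._score([1, 1, -1, -1, 0, 0]).total == 3

    def test_no_run_reaches_length_two(self):
        assert self._score([1, 0, 1]).total == 0

    def test_short_arm_contributes_zero_flagged(self):
        out = self._score([1])
        assert out.total == 0 and out.flagged_arms == ["1"]

    def test_unaltered_genome_equals_arm_count(self):
        layout = mouse_layout({"1": 100 * MB, "2": 100 * MB})
        rows = []
        for chrom in ("1", "2"):
            df = calls_frame([0.0] * 5, chrom=chrom)
            df["gene"] += chrom
            rows.append(df)
        out = copy_state_score(pd.concat(rows, ignore_index=True), layout)
        assert out.total == 2

    def test_order_sensitivity(self):
        """Unlike FGA, the score depends on the genomic ordering of states."""
        assert self._score([1, 1, 0, 0]).total != \
            self._score([1, 0, 1, 0]).total


class TestFloxRatio:
    def test_akp_flfl_ratio_exactly_one(self):
        """Homozygous deletion of both flox targets: ratio 1 at any purity."""
        for p in (0.05, 0.3, 0.7, 0.99):
            v = pd.Series({"Trp53_flox": expected_flox_log2cnr(0, p),
                           "Apc_flox": expected_flox_log2cnr(0, p)})
            assert flox_ratio(v).ratio == pytest.approx(1.0)

    def test_ak_ratio_exactly_zero(self):
        """Intact Trp53 flox: numerator log2CNR 0 -> ratio 0."""
        for p in (0.3, 0.7):
            v = pd.Series({"Trp53_flox": expected_flox_log2cnr(2, p),
                           "Apc_flox": expected_flox_log2cnr(0, p)})
            assert flox_ratio(v).ratio == pytest.approx(0.0)

    def test_akp_heterozygous_low_purity_limit(self):
        """Het Trp53 flox deletion: log2(1-p/2)/log2(1-p) -> 1/2 as p -> 0."""
        v = pd.Series({"Trp53_flox": expected_flox_log2cnr(1, 0.01),
                       "Apc_flox": expected_flox_log2cnr(0, 0.01)})
        assert flox_ratio(v).ratio == pytest.approx(0.5, abs=0.002)

    def test_zero_denominator_undefined(self):
        v = pd.Series({"Trp53_flox": -1.0, "Apc_flox": 0.0})
        with pytest.warns(UserWarning, match="undefined"):
            out = flox_ratio(v)
        assert out.ratio is None

    def test_genotype_regression_recovers_group_means(self):
        rng = np.random.default_rng(3)
        rows = []
        for genotype, mean in [("AK", 0.0), ("AKP_fl", 0.5),
                               ("AKP_flfl", 1.0)]:
            for _ in range(12):
                rows.append({"genotype": genotype,
                             "ratio": mean + rng.normal(0, 0.05)})
        out = genotype_ratio_regression(pd.DataFrame(rows))
        means = out.set_index("genotype")["mean_ratio"]
        assert means["AK"] == pytest.approx(0.0, abs=0.05)
        assert means["AKP_fl"] == pytest.approx(0.5, abs=0.05)
        assert means["AKP_flfl"] == pytest.approx(1.0, abs=0.05)


def hypergeom_two_sided_oracle(table):
    """Exhaustive enumeration of the conditional distribution."""
    a, b = table[0]
    c, d = table[1]
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    probs = {k: stats.hypergeom.pmf(k, n1 + n2, n1, m)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_printed_aneuploidy_table(self):
        """3/16 vs 0/10 two-sided: p = 0.26."""
        res = fisher_exact_2x2([[3, 13], [0, 10]])
        assert res.p == pytest.approx(0.2615, abs=2e-4)

    def test_printed_smad4_table(self):
        """14/28 vs 1/10 one-sided: p ~ 0.03, conditional-MLE OR ~ 8.5."""
        res = fisher_exact_2x2([[14, 14], [1, 9]], alternative="greater")
        assert res.p == pytest.approx(0.028, abs=2e-3)
        assert res.odds_ratio == pytest.approx(8.5, abs=0.1)

    def test_symmetric_table(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res.p == 1.0 and res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_zero_margin(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.odds_ratio is None and res.p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 11, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        res = fisher_exact_2x2(t.tolist())
        assert res.p == pytest.approx(hypergeom_two_sided_oracle(t.tolist()),
                                      rel=1e-9)


ARMS19 = [str(c) for c in range(1, 20)]


class TestRecurrencePermutation:
    def test_all_zero_matrix(self):
        m = pd.DataFrame(0, index=range(10), columns=ARMS19)
        res = recurrent_aneuploidy_permutation(m, n_perm=50, seed=0)
        assert (res["p"] == 1.0).all()

    def test_row_sums_invariant_under_permutation(self):
        from mousecred.credential import _permute_rows
        rng = np.random.default_rng(1)
        m = simulate_aneuploidy_matrix(15, ARMS19, 0.3, seed=2).values
        perm = _permute_rows(m, rng)
        np.testing.assert_array_equal(np.sort(perm, axis=1),
                                      np.sort(m, axis=1))

    def test_planted_recurrent_arm_detected(self):
        m = simulate_aneuploidy_matrix(20, ARMS19[:10], 0.05,
                                       planted={"1": (0.6, 1)}, seed=3)
        res = recurrent_aneuploidy_permutation(m, n_perm=1000, seed=4)
        hit = res[(res["arm"] == "1") & (res["direction"] == "gain")]
        assert hit["q"].iloc[0] < 0.05

    def test_empirical_p_never_zero(self):
        m = simulate_aneuploidy_matrix(20, ARMS19[:10], 0.0,
                                       planted={"1": (0.9, -1)}, seed=5)
        res = recurrent_aneuploidy_permutation(m, n_perm=200, seed=6)
        assert (res["p"] >= 1.0 / 201).all()


class TestArmSpecificity:
    def test_identical_cohorts_or_near_one(self):
        m = simulate_aneuploidy_matrix(100, ARMS19[:6], 0.3, seed=7)
        out = arm_specificity_test(m, {"other": m.copy()})
        assert (out["per_arm"]["q"] > 0.05).all()
        assert out["flagged"] == []

    def test_planted_target_specific_arm_flagged(self):
        target = simulate_aneuploidy_matrix(200, ARMS19[:6], 0.05,
                                            planted={"1": (0.6, 1),
                                                     "2": (0.5, 1)}, seed=8)
        comps = {f"c{i}": simulate_aneuploidy_matrix(
            200, ARMS19[:6], 0.05, seed=20 + i) for i in range(3)}
        out = arm_specificity_test(target, comps)
        assert "1" in out["flagged"] and "2" in out["flagged"]
        assert not out["co_occurrence"].empty

    def test_single_comparison_cohort(self):
        target = simulate_aneuploidy_matrix(200, ARMS19[:4], 0.05,
                                            planted={"1": (0.6, 1)}, seed=9)
        comp = simulate_aneuploidy_matrix(200, ARMS19[:4], 0.05, seed=10)
        out = arm_specificity_test(target, {"only": comp})
        assert "1" in out["flagged"]


def identity_map(mouse_chroms, hchrom="13", hlen=100 * MB):
    n = len(mouse_chroms)
    return pd.DataFrame([
        {"hchrom": hchrom, "hstart": i * hlen // n,
         "hend": (i + 1) * hlen // n, "mchrom": mc, "mstart": 0,
         "mend": hlen // n, "orientation": "+"}
        for i, mc in enumerate(mouse_chroms)])


class TestSyntenyMapping:
    def test_identity_map_full_synteny(self):
        smap = identity_map(["5"])
        out = map_syntenic(("13", 0, 100 * MB), smap)
        assert out["percent_synteny"]["5"] == pytest.approx(1.0)

    def test_even_split_between_two_chromosomes(self):
        smap = identity_map(["14", "5"])
        out = map_syntenic(("13", 0, 100 * MB), smap)
        assert out["percent_synteny"]["14"] == pytest.approx(0.5)
        assert out["percent_synteny"]["5"] == pytest.approx(0.5)

    def test_no_overlap_warns_empty(self):
        smap = identity_map(["5"])
        with pytest.warns(UserWarning, match="no syntenic"):
            out = map_syntenic(("7", 0, 10 * MB), smap)
        assert out["percent_synteny"].empty


HUMAN_COLS = ["13q"] + [f"h{i}" for i in range(10)]
H_ARMS = {"13q": ("13", 0, 100 * MB)}


class TestScenarioTest:
    def test_concordant_favors_scenario_one(self):
        rng = np.random.default_rng(0)
        gains = (rng.random(30) < 0.8).astype(int)
        hm = pd.DataFrame(0, index=range(30), columns=HUMAN_COLS)
        hm["13q"] = gains
        mm = pd.DataFrame(0, index=range(30), columns=ARMS19)
        mm["5"] = gains
        res = synteny_scenario_test(hm, H_ARMS, mm, identity_map(["5"]),
                                    n_perm=500, seed=1)
        assert res["favored"].iloc[0] == 1
        assert res["log_or_s1"].iloc[0] > 0

    def test_planted_subset_favors_scenario_two(self):
        rng = np.random.default_rng(1)
        hm = pd.DataFrame(0, index=range(30), columns=HUMAN_COLS)
        hm["13q"] = (rng.random(30) < 0.4).astype(int)
        mm = pd.DataFrame(0, index=range(28), columns=ARMS19)
        mm["5"] = (rng.random(28) < 0.46).astype(int)
        res = synteny_scenario_test(hm, H_ARMS, mm,
                                    identity_map(["14", "8", "5"]),
                                    n_perm=1000, seed=2)
        assert res["favored"].iloc[0] == 2
        assert res["p_s2_vs_s1"].iloc[0] < 0.05

    def test_independent_matrices_rarely_favor_anything(self):
        """Null calibration: over independent replicates the favored rate
        stays at the false-positive level (alpha = 0.05 per comparison)."""
        favored = []
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            hm = pd.DataFrame((rng.random((30, len(HUMAN_COLS))) < 0.15)
                              .astype(int), columns=HUMAN_COLS)
            mm = pd.DataFrame((rng.random((28, len(ARMS19))) < 0.15)
                              .astype(int), columns=ARMS19)
            res = synteny_scenario_test(hm, H_ARMS, mm,
                                        identity_map(["14", "8", "5"]),
                                        n_perm=300, seed=rep)
            favored.append(res["favored"].iloc[0])
        assert sum(f is not None for f in favored) <= 4

    def test_anticorrelated_favors_scenario_three(self):
        rng = np.random.default_rng(3)
        hm = pd.DataFrame(0, index=range(30), columns=HUMAN_COLS)
        hm["13q"] = (rng.random(30) < 0.8).astype(int)
        mm = pd.DataFrame((rng.random((30, len(ARMS19))) < 0.2).astype(int),
                          columns=ARMS19)
        mm["5"] = 0
        res = synteny_scenario_test(hm, H_ARMS, mm, identity_map(["5"]),
                                    n_perm=500, seed=4)
        assert res["favored"].iloc[0] == 3

    def test_unmapped_arm_skipped_with_warning(self):
        hm = pd.DataFrame(0, index=range(10), columns=HUMAN_COLS)
        mm = pd.DataFrame(0, index=range(10), columns=ARMS19)
        smap = identity_map(["5"], hchrom="7")
        with pytest.warns(UserWarning, match="skipped"):
            res = synteny_scenario_test(hm, H_ARMS, mm, smap, n_perm=50,
                                        seed=5)
        assert res.empty
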