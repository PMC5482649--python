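"""Quality-control filters: boundary behaviour and recovery of injections."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenscan import qc
from burdenscan.qc import MISSING


class TestGenotypeSupport:
    @pytest.mark.parametrize("gt,gq,alt,tranche,is_snv,expect", [
        (1, 30, 4, 99.0, True, True),    # all thresholds just satisfied
        (1, 29, 10, 95.0, True, False),  # GQ below 30
        (1, 60, 3, 95.0, True, False),   # alt depth not strictly > 3
        (1, 60, 10, 99.5, True, False),  # SNV tranche bound is strict
        (1, 60, 10, 99.2, False, False), # indel bound 99 is tighter
        (0, 5, 0, 99.9, True, True),     # reference calls pass trivially
        (MISSING, 5, 0, 99.9, True, True),
    ])
    def test_boundaries(self, gt, gq, alt, tranche, is_snv, expect):
        assert qc.genotype_support_filter(gt, gq, alt, tranche, is_snv) is expect

    def test_vectorised_matches_scalar(self, rng):
        g = rng.integers(-1, 3, (20, 15)).astype(np.int8)
        gq = rng.integers(10, 90, g.shape)
        alt = rng.integers(0, 12, g.shape)
        tranche = rng.uniform(95, 100, 20)
        is_snv = rng.random(20) < 0.5
        out = qc.apply_genotype_support_filter(g, gq, alt, tranche, is_snv)
        for vi in range(20):
            for si in range(15):
                keep = qc.genotype_support_filter(
                    int(g[vi, si]), gq[vi, si], alt[vi, si], tranche[vi],
                    bool(is_snv[vi]),
                )
                assert out[vi, si] == (g[vi, si] if keep else MISSING)


class TestSampleRates:
    def test_missingness_arithmetic(self):
        g = np.zeros((100, 3), dtype=np.int8)
        g[:61, 1] = MISSING
        rates = qc.sample_missingness(g, np.arange(100))
        assert rates[0] == 0.0
        assert rates[1] == pytest.approx(0.61)

    def test_heterozygosity_extremes(self):
        g = np.zeros((50, 2), dtype=np.int8)
        g[:, 1] = 1
        rates = qc.sample_heterozygosity(g, np.arange(50))
        assert rates[0] == 0.0 and rates[1] == 1.0

    def test_rates_match_independent_recount(self, small_cohort):
        co = small_cohort
        sub = co.common_snv_rows
        rates = qc.sample_missingness(co.genotypes, sub)
        # oracle: plain Python recount on a handful of samples
        for si in (0, 5, 100):
            n_miss = sum(
                1 for vi in sub if co.genotypes[vi, si] == MISSING
            )
            assert rates[si] == pytest.approx(n_miss / len(sub))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            qc.sample_missingness(np.zeros((5, 2)), np.array([], dtype=int))


class TestOutliers:
    def test_single_extreme_value_flagged(self):
        v = np.array([0.01] * 99 + [0.5])
        flags = qc.flag_outliers_3sd(v)
        # oracle: direct mean/SD computation
        thr = v.mean() + 3 * v.std(ddof=0)
        assert flags.sum() == 1 and flags[-1]
        assert (v > thr).sum() == 1

    def test_constant_vector_unflagged(self):
        assert not qc.flag_outliers_3sd(np.full(10, 0.3)).any()

    def test_k_zero_flags_above_mean(self):
        v = np.array([1.0, 2.0, 3.0])
        assert list(qc.flag_outliers_3sd(v, k=0)) == [False, False, True]


class TestSexCheck:
    def test_reported_female_without_x_heterozygosity_flagged(self, rng):
        # 200 X sites, MAF ~0.3; sample 0 hemizygous-coded (no hets)
        maf = rng.uniform(0.2, 0.5, 200)
        females = rng.binomial(2, maf[:, None], (200, 30)).astype(np.int8)
        hemi = 2 * rng.binomial(1, maf[:, None], (200, 1)).astype(np.int8)
        x = np.hstack([hemi, females])
        reported = np.array(["F"] + ["F"] * 30, dtype=object)
        out = qc.sex_check(x, reported)
        assert out.loc[0, "sex_discrepancy"]
        assert out.loc[0, "inferred_sex"] == "M"
        assert not out["sex_discrepancy"][1:].any()

    def test_reported_male_without_hets_passes(self, rng):
        maf = rng.uniform(0.2, 0.5, 200)
        x = 2 * rng.binomial(1, maf[:, None], (200, 5)).astype(np.int8)
        out = qc.sex_check(x, np.array(["M"] * 5, dtype=object))
        assert not out["sex_discrepancy"].any()

    def test_unknown_reported_never_flagged(self, rng):
        maf = rng.uniform(0.2, 0.5, 100)
        x = rng.binomial(2, maf[:, None], (100, 4)).astype(np.int8)
        out = qc.sex_check(x, np.array(["unknown"] * 4, dtype=object))
        assert not out["sex_discrepancy"].any()

    def test_no_x_variants_undetermined(self):
        out = qc.sex_check(
            np.zeros((0, 3), dtype=np.int8), np.array(["M", "F", "M"], object)
        )
        assert (out["inferred_sex"] == "undetermined").all()
        assert not out["sex_discrepancy"].any()


class TestDuplicates:
    def test_planted_exact_duplicate_detected(self, rng):
        g = rng.binomial(2, 0.3, (300, 10)).astype(np.int8)
        g[:, 7] = g[:, 2]
        miss = qc.sample_missingness(g, np.arange(300))
        pairs = qc.detect_duplicates(g, np.arange(300), miss)
        assert pairs == [(2, 7)]

    def test_unrelated_samples_below_threshold(self, small_cohort):
        co = small_cohort
        miss = qc.sample_missingness(co.genotypes, co.common_snv_rows)
        pairs = qc.detect_duplicates(
            co.genotypes, co.common_snv_rows, miss
        )
        assert pairs == []  # no duplicates were injected


class TestHweExact:
    @staticmethod
    def brute_force_hwe(n_homref, n_het, n_homalt):
        """Oracle: rational enumeration with exact integer combinatorics."""
        n = n_homref + n_het + n_homalt
        n_alt = n_het + 2 * n_homalt
        n_rare = min(n_alt, 2 * n - n_alt)
        probs = {}
        for h in range(n_rare % 2, n_rare + 1, 2):
            rare_hom = (n_rare - h) // 2
            com_hom = n - h - rare_hom
            if com_hom < 0:
                continue
            probs[h] = Fraction(
                2 ** h * math.factorial(n),
                math.factorial(h) * math.factorial(rare_hom) * math.factorial(com_hom),
            ) * Fraction(
                math.factorial(n_rare) * math.factorial(2 * n - n_rare),
                math.factorial(2 * n),
            )
        p_obs = probs[n_het]
        return float(sum(p for p in probs.values() if p <= p_obs))

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (40, 20, 40), (5, 0, 5), (90, 9, 1), (0, 10, 0),
        (12, 1, 12), (3, 7, 2),
    ])
    def test_matches_rational_enumeration(self, counts):
        got = qc.hwe_exact_test(*counts)
        want = self.brute_force_hwe(*counts)
        assert got == pytest.approx(want, rel=1e-9)

    def test_all_het_extreme_deviation(self):
        assert qc.hwe_exact_test(0, 100, 0) < 1e-8

    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(50, 0, 0) == 1.0

    def test_zero_genotypes(self):
        assert qc.hwe_exact_test(0, 0, 0) == 1.0

    def test_all_hom_alt_carriers_violate(self):
        # the injected failure shape: carriers exclusively homozygous
        assert qc.hwe_exact_test(492, 0, 8) < 1e-8

    def test_chi2_variant_agrees_on_large_balanced(self):
        p_exact = qc.hwe_exact_test(250, 500, 250)
        p_chi2 = qc.hwe_chi2_test(250, 500, 250)
        assert p_exact > 0.5 and p_chi2 > 0.5


class TestAlleleBalance:
    def test_perfect_balance_retained(self):
        assert qc.allele_balance_test(10, 10) == 1.0

    @pytest.mark.parametrize("ref,alt", [(30, 2), (12, 8), (50, 14)])
    def test_matches_chi2_survival(self, ref, alt):
        want = stats.chi2.sf((ref - alt) ** 2 / (ref + alt), 1)
        assert qc.allele_balance_test(ref, alt) == pytest.approx(want)

    def test_heavy_imbalance_below_threshold(self):
        assert qc.allele_balance_test(30, 2) < 1e-4

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            qc.allele_balance_test(0, 0)

    def test_filter_removes_only_imbalanced_hets(self):
        g = np.array([[1, 1, 0, 2]], dtype=np.int8)
        ref = np.array([[30, 10, 40, 0]])
        alt = np.array([[2, 10, 0, 40]])
        out = qc.apply_allele_balance_filter(g, ref, alt)
        assert list(out[0]) == [MISSING, 1, 0, 2]


class TestDifferentialMissingness:
    def test_identical_rates_give_one(self):
        assert qc.differential_missingness_test(90, 10, 900, 100) == pytest.approx(
            1.0, abs=0.05
        )

    def test_matches_scipy_oracle(self):
        want = stats.fisher_exact([[400, 113], [1560, 9]])[1]
        got = qc.differential_missingness_test(400, 113, 1560, 9)
        assert got == pytest.approx(want, rel=1e-6)
        assert got < 1e-5

    def test_no_missing_anywhere(self):
        assert qc.differential_missingness_test(500, 0, 1500, 0) == 1.0


def _ann(n, **overrides):
    base = {
        "alignability": np.ones(n),
        "repeat_distance": np.full(n, 1000),
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestVariantTracks:
    def test_alignability_and_repeat_rules(self, rng):
        g = rng.binomial(2, 0.2, (3, 200)).astype(np.int8)
        case = np.arange(200) < 60
        ann = _ann(3)
        ann.loc[0, "alignability"] = 0.5
        ann.loc[1, "repeat_distance"] = 10   # inclusive: fails
        ann.loc[2, "repeat_distance"] = 11   # just outside: passes
        rep = qc.single_variant_qc(g, case, ann)
        assert not rep.loc[0, "alignability_pass"]
        assert not rep.loc[1, "repeat_distance_pass"]
        assert rep.loc[2, "repeat_distance_pass"]

    def test_no_call_rate_bounds_differ_by_track(self):
        # 26% no-calls in cases: gene-centric fails (>=25%), and the
        # single-variant bound (3%) fails far earlier
        g = np.zeros((1, 400), dtype=np.int8)
        case = np.arange(400) < 100
        g[0, :26] = MISSING
        ann = _ann(1)
        sv = qc.single_variant_qc(g, case, ann)
        gc = qc.gene_centric_qc(g, case, ann)
        assert not sv.loc[0, "no_call_rate_pass"]
        assert not gc.loc[0, "no_call_rate_pass"]
        # exactly 25% is still a gene-centric failure (inclusive bound)
        g2 = np.zeros((1, 400), dtype=np.int8)
        g2[0, :25] = MISSING
        gc2 = qc.gene_centric_qc(g2, case, _ann(1))
        assert not gc2.loc[0, "no_call_rate_pass"]
        g3 = np.zeros((1, 400), dtype=np.int8)
        g3[0, :24] = MISSING
        gc3 = qc.gene_centric_qc(g3, case, _ann(1))
        assert gc3.loc[0, "no_call_rate_pass"]

    def test_hwe_track_thresholds(self):
        # combined HWE P ~ 1e-7: passes gene-centric (1e-8), fails
        # single-variant (1e-5) when present in one group
        case = np.arange(400) < 100
        g = np.zeros((1, 400), dtype=np.int8)
        g[0, 100:107] = 2  # 7 hom-alt controls, no hets
        p_ctrl = qc.hwe_exact_test(293, 0, 7)
        rep_sv = qc.single_variant_qc(g, case, _ann(1))
        rep_gc = qc.gene_centric_qc(g, case, _ann(1))
        assert p_ctrl < 1e-5
        assert not rep_sv.loc[0, "hwe_pass"]
        p_comb = qc.hwe_exact_test(393, 0, 7)
        assert rep_gc.loc[0, "hwe_pass"] == (p_comb >= 1e-8)

    def test_missing_annotation_columns_rejected(self):
        with pytest.raises(ValueError):
            qc.single_variant_qc(
                np.zeros((1, 10), dtype=np.int8), np.arange(10) < 5,
                pd.DataFrame({"alignability": [1.0]}),
            )

    def test_order_independence(self, rng):
        g = rng.binomial(2, 0.1, (8, 100)).astype(np.int8)
        case = np.arange(100) < 30
        ann = _ann(8)
        rep = qc.single_variant_qc(g, case, ann)
        perm = rng.permutation(8)
        rep_p = qc.single_variant_qc(g[perm], case, ann.iloc[perm].reset_index(drop=True))
        assert list(rep["variant_pass"].to_numpy()[perm]) == list(
            rep_p["variant_pass"]
        )


class TestFailureRecovery:
    """Every injected QC failure mode is recovered by its detector."""

    def test_injected_sample_failures_flagged(self, failure_cohort):
        co = failure_cohort
        truth = co.truth.failures
        report = qc.sample_qc(
            co.genotypes, co.common_snv_rows, co.genotypes[co.x_rows],
            co.samples,
        )
        t = report.table.set_index("sample_id")
        for sid in truth.get("missingness_outlier", []):
            assert t.loc[sid, "high_missingness"]
        for sid in truth.get("heterozygosity_outlier", []):
            assert t.loc[sid, "high_heterozygosity"]
        for sid in truth.get("sex_mismatch", []):
            assert t.loc[sid, "sex_discrepancy"]
        detected_pairs = {
            frozenset((report.table.loc[i, "sample_id"],
                       report.table.loc[j, "sample_id"]))
            for i, j in report.duplicate_pairs
        }
        for a, b in truth.get("duplicate_pair", []):
            assert frozenset((a, b)) in detected_pairs

    def test_injected_hwe_sites_fail_gene_centric(self, failure_cohort):
        co = failure_cohort
        keys = co.variants["variant_key"].to_numpy()
        ann = co.annotations.set_index("variant_key").loc[keys].reset_index()
        rep = qc.gene_centric_qc(co.genotypes, co.case_mask, ann)
        rep = rep.assign(variant_key=keys).set_index("variant_key")
        for key in co.truth.failures.get("hwe_violating_site", []):
            assert not rep.loc[key, "hwe_pass"]

    def test_injected_repeat_sites_fail(self, failure_cohort):
        co = failure_cohort
        keys = co.variants["variant_key"].to_numpy()
        ann = co.annotations.set_index("variant_key").loc[keys].reset_index()
        rep = qc.single_variant_qc(co.genotypes, co.case_mask, ann)
        rep = rep.assign(variant_key=keys).set_index("variant_key")
        for key in co.truth.failures.get("repeat_proximal_site", []):
            assert not rep.loc[key, "repeat_distance_pass"]

    def test_exclusion_total_deduplicates(self, failure_cohort):
        co = failure_cohort
        report = qc.sample_qc(
            co.genotypes, co.common_snv_rows, co.genotypes[co.x_rows],
            co.samples,
        )
        s = report.exclusion_summary()
        flagged = report.table[
            ["sex_discrepancy", "high_missingness", "high_heterozygosity",
             "ancestry_excluded", "duplicate"]
        ].any(axis=1).sum()
        assert s["total_excluded"] == int(flagged)
        assert s["total_excluded"] <= sum(
            v for k, v in s.items() if k != "total_excluded"
        )
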