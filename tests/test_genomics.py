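"""Copy-number burden, arm aneuploidy, mutation filtering, signatures."""

import numpy as np
import pandas as pd
import pytest

from immunodissect.contexts import synthetic_reference_signatures
from immunodissect.genomics import (
    aneuploidy_score,
    autosomal_arm_table,
    call_gains_losses,
    context_count_matrix,
    differential_alteration_test,
    extract_mutational_signatures,
    fraction_genome_altered,
    leukocyte_cnv_correlation,
    mutation_frequency_filter,
)
from immunodissect.synthetic import generate_mutation_catalog


def _seg(rows):
    return pd.DataFrame(
        rows, columns=["sample", "chromosome", "start", "end", "seg_mean"]
    )


class TestGainsLosses:
    GENES = pd.DataFrame(
        [{"gene": "GX", "chromosome": "1", "start": 100, "end": 299}]
    )

    @pytest.mark.parametrize(
        "seg_mean,expected",
        [(0.31, "gain"), (0.30, "neutral"), (-0.31, "loss"), (-0.30, "neutral")],
    )
    def test_strict_thresholds(self, seg_mean, expected):
        seg = _seg([("s1", "1", 1, 1000, seg_mean)])
        calls = call_gains_losses(seg, self.GENES)
        assert calls.iloc[0]["call"] == expected

    def test_half_covered_weighted_mean_is_neutral(self):
        # gene 100..299: half at +0.6, half at 0.0 -> mean 0.3 -> neutral
        seg = _seg([("s1", "1", 100, 199, 0.6), ("s1", "1", 200, 299, 0.0)])
        calls = call_gains_losses(seg, self.GENES)
        assert calls.iloc[0]["weighted_mean"] == pytest.approx(0.3)
        assert calls.iloc[0]["call"] == "neutral"

    def test_uncovered_gene_neutral_with_flag(self):
        seg = _seg([("s1", "2", 1, 1000, 1.0)])
        calls = call_gains_losses(seg, self.GENES)
        assert calls.iloc[0]["call"] == "neutral"
        assert bool(calls.iloc[0]["missing_data"])


class TestFractionGenomeAltered:
    def test_all_neutral_is_zero(self):
        seg = _seg([("s1", "1", 1, 100, 0.0), ("s1", "2", 1, 100, 0.05)])
        res = fraction_genome_altered(seg)
        assert res.loc["s1", "fraction_altered"] == 0.0

    def test_hand_computed_quarter(self):
        # lengths 100 and 300 at 0.2 / 0.05 -> 100/400 = 0.25
        seg = _seg([("s1", "1", 1, 100, 0.2), ("s1", "1", 101, 400, 0.05)])
        res = fraction_genome_altered(seg)
        assert res.loc["s1", "fraction_altered"] == pytest.approx(0.25)

    def test_fully_altered_both_signs(self):
        seg = _seg([("s1", "1", 1, 50, -0.5), ("s1", "1", 51, 100, 0.5)])
        res = fraction_genome_altered(seg)
        assert res.loc["s1", "fraction_altered"] == pytest.approx(1.0)
        assert res.loc["s1", "n_segments"] == 2

    def test_invariant_to_splitting_segments(self):
        seg = _seg([("s1", "1", 1, 1000, 0.4), ("s1", "2", 1, 500, 0.0)])
        split = _seg(
            [
                ("s1", "1", 1, 600, 0.4),
                ("s1", "1", 601, 1000, 0.4),
                ("s1", "2", 1, 500, 0.0),
            ]
        )
        a = fraction_genome_altered(seg).loc["s1", "fraction_altered"]
        b = fraction_genome_altered(split).loc["s1", "fraction_altered"]
        assert a == pytest.approx(b)


class TestAneuploidy:
    ARMS = pd.DataFrame(
        [
            {"arm": "1p", "chromosome": "1", "start": 1, "end": 1000},
            {"arm": "1q", "chromosome": "1", "start": 1001, "end": 2000},
        ]
    )

    def test_all_zero_scores_zero(self):
        seg = _seg([("s1", "1", 1, 2000, 0.0)])
        res = aneuploidy_score(seg, self.ARMS)
        assert res.loc["s1", "aneuploidy_score"] == 0

    def test_one_amplified_arm(self):
        seg = _seg([("s1", "1", 1, 1000, 0.4), ("s1", "1", 1001, 2000, 0.0)])
        res = aneuploidy_score(seg, self.ARMS)
        assert res.loc["s1", "aneuploidy_score"] == 1

    def test_balanced_arm_not_counted(self):
        # half +0.4 / half -0.4 -> weighted mean 0 -> arm not counted
        seg = _seg([("s1", "1", 1, 500, 0.4), ("s1", "1", 501, 1000, -0.4),
                    ("s1", "1", 1001, 2000, 0.0)])
        res = aneuploidy_score(seg, self.ARMS)
        assert res.loc["s1", "aneuploidy_score"] == 0

    def test_default_arm_table_shape(self):
        arms = autosomal_arm_table()
        assert len(arms) == 39  # 22 autosomes x 2 minus 5 acrocentric p arms
        assert (arms["end"] > arms["start"]).all()


class TestMutationFrequency:
    def _catalog(self, gene_sample_pairs, classification="Missense_Mutation"):
        return pd.DataFrame(
            [
                {"Hugo_Symbol": g, "Tumor_Sample_Barcode": s,
                 "Variant_Classification": classification}
                for g, s in gene_sample_pairs
            ]
        )

    def test_above_threshold_retained(self):
        cat = self._catalog([("TP53", f"s{i}") for i in range(6)])
        assert mutation_frequency_filter(cat, n_samples=100) == ["TP53"]

    def test_exactly_at_threshold_excluded(self):
        cat = self._catalog([("TP53", f"s{i}") for i in range(5)])
        assert mutation_frequency_filter(cat, n_samples=100) == []

    def test_recurrent_hits_in_one_sample_count_once(self):
        pairs = [("KRAS", "s0")] * 10 + [("KRAS", f"s{i}") for i in range(1, 5)]
        cat = self._catalog(pairs)
        # 5 distinct samples of 100 -> not > 5% -> excluded
        assert mutation_frequency_filter(cat, n_samples=100) == []

    def test_silent_records_ignored(self):
        cat = self._catalog(
            [("GENE", f"s{i}") for i in range(20)], classification="Silent"
        )
        assert mutation_frequency_filter(cat, n_samples=100) == []

    def test_empty_catalog(self):
        assert mutation_frequency_filter(pd.DataFrame(), n_samples=10) == []


class TestSignatureExtraction:
    def test_two_signature_catalog_recovered(self):
        ref = synthetic_reference_signatures()
        rng = np.random.default_rng(11)
        mix = rng.uniform(0.2, 0.8, 50)
        expo = pd.DataFrame(0.0, index=ref.columns,
                            columns=[f"M{i}" for i in range(50)])
        expo.loc["apobec_tcw_cg"] = mix
        expo.loc["aging_cpg_ct"] = 1 - mix
        cat = generate_mutation_catalog(expo, 400, ref, seed=12)
        counts = context_count_matrix(cat)
        res = extract_mutational_signatures(counts, k=2, seed=1, reference=ref)
        best = res["match"][["apobec_tcw_cg", "aging_cpg_ct"]].max(axis=0)
        assert (best >= 0.9).all()

    def test_single_signature_high_cosine(self):
        ref = synthetic_reference_signatures()
        expo = pd.DataFrame(0.0, index=ref.columns,
                            columns=[f"M{i}" for i in range(30)])
        expo.loc["smoking_ca"] = 1.0
        cat = generate_mutation_catalog(expo, 500, ref, seed=4)
        counts = context_count_matrix(cat)
        res = extract_mutational_signatures(counts, k=1, seed=2, reference=ref)
        assert res["match"].loc["extracted_0", "smoking_ca"] >= 0.98

    def test_exposures_reconstruct_totals(self):
        ref = synthetic_reference_signatures()
        expo = pd.DataFrame(0.0, index=ref.columns,
                            columns=[f"M{i}" for i in range(25)])
        expo.loc["flat"] = 0.5
        expo.loc["aging_cpg_ct"] = 0.5
        cat = generate_mutation_catalog(expo, 300, ref, seed=5)
        counts = context_count_matrix(cat)
        res = extract_mutational_signatures(counts, k=2, seed=0)
        recon = res["signatures"].to_numpy() @ res["exposures"].to_numpy()
        observed = counts.to_numpy().sum(axis=0)
        assert (res["exposures"].to_numpy() >= 0).all()
        np.testing.assert_allclose(
            recon.sum(axis=0), observed, rtol=0.01
        )


class TestDifferentialAlteration:
    def test_exclusive_alteration_is_extreme(self):
        altered = pd.DataFrame(
            [[True] * 20 + [False] * 20], index=["f"],
            columns=[f"s{i}" for i in range(40)],
        )
        groups = pd.Series(
            ["A"] * 20 + ["B"] * 20, index=altered.columns
        )
        res = differential_alteration_test(altered, groups)
        assert res.loc["f", "p_value"] < 1e-6

    def test_identical_rates_p_one(self):
        altered = pd.DataFrame(
            [[True] * 10 + [False] * 10 + [True] * 10 + [False] * 10],
            index=["f"], columns=[f"s{i}" for i in range(40)],
        )
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=altered.columns)
        res = differential_alteration_test(altered, groups)
        assert res.loc["f", "p_value"] == pytest.approx(1.0)

    def test_null_simulation_bh_control(self, rng):
        n_feat, n = 500, 60
        altered = pd.DataFrame(
            rng.random((n_feat, n)) < 0.3,
            index=[f"f{i:03d}" for i in range(n_feat)],
            columns=[f"s{i}" for i in range(n)],
        )
        groups = pd.Series(["A"] * 30 + ["B"] * 30, index=altered.columns)
        res = differential_alteration_test(altered, groups)
        assert (res["adj_p"] < 0.05).sum() <= 0.05 * n_feat


class TestLeukocyteCorrelation:
    def test_perfect_negative(self):
        x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        res = leukocyte_cnv_correlation(x, -x)
        assert res.loc["pooled", "spearman_rho"] == pytest.approx(-1.0)

    def test_planted_negative_correlation_recovered(self, rng):
        n = 150
        z = rng.normal(size=n)
        x = z + rng.normal(scale=1.4, size=n)
        y = -z + rng.normal(scale=1.4, size=n)  # target rank corr ~ -0.34
        idx = [f"s{i}" for i in range(n)]
        res = leukocyte_cnv_correlation(
            pd.Series(x, index=idx), pd.Series(y, index=idx)
        )
        assert res.loc["pooled", "spearman_rho"] == pytest.approx(-0.34, abs=0.15)

    def test_constant_vector_rejected(self):
        idx = [f"s{i}" for i in range(10)]
        with pytest.raises(ValueError, match="constant"):
            leukocyte_cnv_correlation(
                pd.Series(1.0, index=idx), pd.Series(np.arange(10.0), index=idx)
            )
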