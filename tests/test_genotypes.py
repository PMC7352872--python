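"""Genotype encoding, Hardy-Weinberg exact test and the filter funnel."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import thermopain as tp
from thermopain.cohort import write_vcf
from thermopain.genotypes import (GenotypeMatrix, locus_shannon_info,
                                  read_genotype_table, read_vcf)


def make_matrix(codes_by_locus, genes=None, controls=None):
    codes = pd.DataFrame({k: np.asarray(v, float) for k, v in codes_by_locus.items()})
    codes.index = pd.Index([f"S{i}" for i in range(len(codes))], name="subject")
    loci = list(codes_by_locus)
    info = pd.DataFrame(
        {
            "gene": genes or ["GENE1"] * len(loci),
            "chrom": "1",
            "pos": np.arange(len(loci)) + 100,
            "vclass": "SNV",
            "dbsnp": [f"rs{i}" for i in range(len(loci))],
            "is_control": controls or [False] * len(loci),
        },
        index=pd.Index(loci, name="locus"),
    )
    return GenotypeMatrix(codes, info)


def hwe_oracle(n0, n1, n2):
    """Exact HWE p by enumeration with rational arithmetic."""
    n = n0 + n1 + n2
    na = n1 + 2 * n2  # variant-allele count
    configs = []
    for m1 in range(na % 2, min(na, n) + 1, 2):
        m2 = (na - m1) // 2
        m0 = n - m1 - m2
        if m0 < 0 or m2 < 0:
            continue
        weight = Fraction(2) ** m1 * Fraction(
            math.factorial(n),
            math.factorial(m0) * math.factorial(m1) * math.factorial(m2))
        configs.append((m1, weight))
    total = sum(w for _, w in configs)
    obs = dict(configs)[n1]
    return float(sum(w for _, w in configs if w <= obs) / total)


class TestHweExactTest:
    def test_all_minor_alleles_heterozygous_is_most_probable(self):
        assert tp.hwe_exact_test(9998, 2, 0) == pytest.approx(1.0)

    def test_extreme_heterozygote_deficit(self):
        assert tp.hwe_exact_test(10, 0, 10) < 1e-5
        assert tp.hwe_exact_test(10, 0, 10) == pytest.approx(
            hwe_oracle(10, 0, 10), rel=1e-9)

    def test_monomorphic_convention(self):
        assert tp.hwe_exact_test(50, 0, 0) == 1.0
        assert tp.hwe_exact_test(0, 0, 50) == 1.0

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for n0 in range(n + 1):
                for n1 in range(n - n0 + 1):
                    n2 = n - n0 - n1
                    assert tp.hwe_exact_test(n0, n1, n2) == pytest.approx(
                        hwe_oracle(n0, n1, n2), rel=1e-9), (n0, n1, n2)

    def test_pvalues_subuniform_under_null(self, rng):
        # type-I calibration: CDF of p on HWE loci at or below the diagonal
        q, n = 0.3, 300
        pvals = []
        for _ in range(400):
            g = rng.binomial(2, q, size=n)
            pvals.append(tp.hwe_exact_test(*(int((g == k).sum()) for k in range(3))))
        pvals = np.sort(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(pvals <= alpha) <= alpha + 0.03


class TestHweFilter:
    def test_planted_heterozygote_free_loci_removed(self, rng):
        cols = {f"L{i}": 2 * rng.binomial(1, 0.5, size=200) for i in range(5)}
        filtered, report = tp.hwe_filter(make_matrix(cols), alpha=0.05)
        assert filtered.n_loci == 0
        assert (report["hwe_p"] < 1e-10).all()

    def test_alpha_zero_removes_nothing(self, rng):
        cols = {f"L{i}": rng.binomial(2, 0.4, size=100) for i in range(10)}
        filtered, _ = tp.hwe_filter(make_matrix(cols), alpha=0.0)
        assert filtered.n_loci == 10

    def test_removal_rate_near_alpha_for_conforming_loci(self, rng):
        cols = {f"L{i}": rng.binomial(2, 0.3, size=1000) for i in range(200)}
        _, report = tp.hwe_filter(make_matrix(cols), alpha=0.05)
        assert report["removed"].mean() <= 0.05 + 0.02


class TestShannonInfo:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 3, 2), math.log(2)),        # p1 = 0.5: maximum entropy
            ((10, 0, 0), 0.0),               # p1 = 0: convention
            ((8, 1, 1), 0.5004024),          # p1 = 0.2: closed form
        ],
    )
    def test_closed_form(self, counts, expected):
        assert tp.shannon_info(*counts) == pytest.approx(expected, abs=1e-6)

    def test_allele_mode(self):
        # allele frequency (2+2)/20 = 0.2 vs carrier fraction 3/10
        assert tp.shannon_info(7, 2, 1, mode="allele") == pytest.approx(
            -0.8 * math.log(0.8) - 0.2 * math.log(0.2))


class TestInformativeFilter:
    def test_rare_loci_fall_in_c_common_in_a(self, rng):
        cols = {}
        for i in range(10):  # common, p1 around 0.4
            cols[f"common{i}"] = rng.binomial(2, 0.25, size=67)
        for i in range(10):  # single carrier among 67
            codes = np.zeros(67)
            codes[i] = 1
            cols[f"rare{i}"] = codes
        filtered, report = tp.informative_filter(make_matrix(cols))
        sets = report["set"]
        assert (sets[[f"rare{i}" for i in range(10)]] == "C").all()
        assert all(l.startswith("common") for l in filtered.loci)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            tp.informative_filter(make_matrix({}))


class TestChi2Effect:
    def test_equal_frequencies_give_zero(self):
        m = make_matrix({"L0": [1, 1, 0, 1, 1, 0]})
        chi2 = tp.chi2_effect(m, [1, 1, 1, 2, 2, 2])
        assert chi2["L0"] == 0.0

    def test_hand_computed_contingency(self):
        # cluster 1 alleles: 20 ref / 10 variant; cluster 2: 10 ref / 20 variant
        c1 = [1] * 10 + [0] * 5
        c2 = [2] * 10 + [0] * 5
        m = make_matrix({"L0": c1 + c2})
        chi2 = tp.chi2_effect(m, [1] * 15 + [2] * 15)
        assert chi2["L0"] == pytest.approx(20 / 3, abs=1e-10)

    def test_monomorphic_locus_scores_zero(self):
        m = make_matrix({"L0": [0] * 8})
        assert tp.chi2_effect(m, [1] * 4 + [2] * 4)["L0"] == 0.0

    def test_matches_scipy_contingency_oracle(self, rng):
        from scipy.stats import chi2_contingency

        codes = rng.binomial(2, rng.uniform(0.1, 0.5, size=20), size=(50, 20))
        m = make_matrix({f"L{i}": codes[:, i] for i in range(20)})
        labels = np.repeat([1, 2], [30, 20])
        mine = tp.chi2_effect(m, labels)
        for i, locus in enumerate(m.loci):
            var = np.array([codes[labels == g, i].sum() for g in (1, 2)])
            tot = np.array([2 * (labels == g).sum() for g in (1, 2)])
            table = np.column_stack([tot - var, var])
            if (table.sum(axis=0) == 0).any():
                expected = 0.0
            else:
                expected = chi2_contingency(table, correction=False).statistic
            assert mine[locus] == pytest.approx(expected, abs=1e-9)


class TestClusterAlleleFrequencies:
    def test_direct_count(self):
        m = make_matrix({"L0": [0, 1, 2, 2, 0, 0, 0, 0]})
        freqs = tp.cluster_allele_frequencies(m, [1, 1, 1, 1, 2, 2, 2, 2])
        assert freqs.loc["L0", "freq_cluster_1_pct"] == pytest.approx(62.5)
        assert freqs.loc["L0", "freq_cluster_2_pct"] == 0.0

    def test_synthetic_design_frequencies_recovered(self):
        spec = tp.CohortSpec(seed=42, assoc_freqs=((0.39, 0.66),) * 8)
        _, labels, matrix = tp.generate_cohort(spec)
        assoc = matrix.info.index[matrix.info["kind"] == "assoc"]
        freqs = tp.cluster_allele_frequencies(matrix.subset_loci(assoc), labels)
        assert np.allclose(freqs["freq_cluster_1_pct"], 39, atol=10)
        assert np.allclose(freqs["freq_cluster_2_pct"], 66, atol=10)


class TestEffectSizeFilter:
    def test_planted_loci_retained(self):
        kept = []
        for seed in range(20):
            spec = tp.CohortSpec(seed=seed, n_assoc_loci=8, n_null_loci=200,
                                 n_rare_loci=0, n_hwe_violating_loci=0,
                                 n_control_loci=0)
            _, labels, matrix = tp.generate_cohort(spec)
            filtered, _ = tp.effect_size_filter(matrix, labels)
            planted = set(matrix.info.index[matrix.info["kind"] == "assoc"])
            kept.append(len(planted & set(filtered.loci)) / len(planted))
        assert np.mean(kept) >= 0.80

    def test_permuted_labels_show_no_enrichment(self, rng):
        from scipy.stats import fisher_exact

        enriched = 0
        for seed in range(20):
            spec = tp.CohortSpec(seed=seed, n_assoc_loci=8, n_null_loci=200,
                                 n_rare_loci=0, n_hwe_violating_loci=0,
                                 n_control_loci=0)
            _, labels, matrix = tp.generate_cohort(spec)
            perm = rng.permutation(labels)
            filtered, _ = tp.effect_size_filter(matrix, perm)
            planted = matrix.info["kind"] == "assoc"
            inside = matrix.info.index.isin(filtered.loci)
            table = [
                [(planted & inside).sum(), (planted & ~inside).sum()],
                [(~planted & inside).sum(), (~planted & ~inside).sum()],
            ]
            if fisher_exact(table, alternative="greater")[1] < 0.05:
                enriched += 1
        assert enriched <= 2  # no enrichment in >= 90% of seeds

    def test_single_locus_retained(self):
        m = make_matrix({"L0": [0, 0, 1, 2, 2, 2]})
        filtered, _ = tp.effect_size_filter(m, [1, 1, 1, 2, 2, 2])
        assert list(filtered.loci) == ["L0"]


class TestReaders:
    def test_variant_class_summary_percentages(self):
        info = pd.DataFrame({"vclass": ["SNV"] * 787 + ["Del"] * 109
                             + ["Ins"] * 86 + ["MIX"] * 18})
        summary = tp.variant_class_summary(info)
        assert summary["SNV"] == pytest.approx(78.7)
        assert summary["Del"] == pytest.approx(10.9)
        assert summary.sum() == pytest.approx(100.0)

    def test_vcf_round_trip_identity(self, planted_cohort, tmp_path):
        _, _, _, matrix = planted_cohort
        matrix = matrix.subset_loci(matrix.loci)  # copy
        matrix.codes.iloc[2, 4] = np.nan  # missing call survives the trip
        write_vcf(matrix, tmp_path / "g.vcf")
        back = read_vcf(tmp_path / "g.vcf")
        assert list(back.loci) == list(matrix.loci)
        assert np.array_equal(back.codes.to_numpy(), matrix.codes.to_numpy(),
                              equal_nan=True)
        assert (back.info["vclass"] == matrix.info["vclass"]).all()
        assert (back.info["is_control"] == matrix.info["is_control"]).all()

    def test_tabular_round_trip(self, planted_cohort, tmp_path):
        _, _, _, matrix = planted_cohort
        matrix.to_tsv(tmp_path / "codes.tsv", tmp_path / "info.tsv")
        back = read_genotype_table(tmp_path / "codes.tsv", tmp_path / "info.tsv")
        pd.testing.assert_frame_equal(back.codes, matrix.codes)
        assert (back.info["gene"] == matrix.info["gene"]).all()

    def test_gt_coding_and_deletion_class(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=17>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD\n"
            "17\t100\trs1\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
            "17\t200\trs2\tTAGT\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t1/1\n"
        )
        m = read_vcf(vcf)
        first = m.codes.iloc[:, 0].to_numpy()
        assert np.array_equal(first[:3], [0, 1, 2]) and np.isnan(first[3])
        assert m.info["vclass"].tolist() == ["SNV", "Del"]


class TestFunnel:
    def test_funnel_order_and_monotonicity(self, planted_cohort):
        _, _, labels, matrix = planted_cohort
        filtered, funnel = tp.preprocess_genotypes(matrix, labels)
        s = funnel.summary()
        assert s["input"] >= s["post_hwe"] >= s["post_shannon"] >= s["post_chi2"]
        assert filtered.n_loci == s["post_chi2"]
        # filters never touch subjects
        assert filtered.n_subjects == matrix.n_subjects
        # HWE-violating planted loci are gone
        violating = matrix.info.index[matrix.info["kind"] == "hwe_violating"]
        assert not set(violating) & set(filtered.loci)
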