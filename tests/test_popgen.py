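"""SNP diversity statistics: both conventions, HWE chi-square, report table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imf.popgen import (
    DiversityStats,
    GenotypeCounts,
    allele_freqs,
    diversity_stats,
    effective_alleles,
    heterozygosity,
    hwe_chisq,
    load_table1_fixture,
    pic_botstein,
    table_report,
)


class TestAlleleFreqs:
    def test_exact_sth(self, sth_counts):
        p, q = allele_freqs(sth_counts, "exact")
        assert p == pytest.approx(24 / 50) and q == pytest.approx(26 / 50)

    def test_rounded_cascade_f1(self, f1_counts):
        # genotype freqs round to (0.40, 0.47, 0.13); p = 0.40 + 0.235 -> 0.64
        p, q = allele_freqs(f1_counts, "paper_rounded")
        assert (p, q) == (0.64, pytest.approx(0.36))

    def test_rounded_cascade_pooled_half_up(self, sth_counts, f1_counts):
        pooled = sth_counts.pooled_with(f1_counts)
        # 18/55 -> 0.33, 26/55 -> 0.47; 0.33 + 0.235 = 0.565 rounds HALF-UP to 0.57
        p, _ = allele_freqs(pooled, "paper_rounded")
        assert p == 0.57

    def test_monomorphic(self):
        p, q = allele_freqs(GenotypeCounts("l", "x", 10, 0, 0))
        assert (p, q) == (1.0, 0.0)

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCounts("l", "x", 0, 0, 0)


class TestHeterozygosity:
    def test_expected_het_sth(self, sth_counts):
        *_, het_exp = heterozygosity(sth_counts, "exact")
        assert het_exp == pytest.approx(1 - (0.48**2 + 0.52**2))  # 0.4992

    def test_observed_f1(self, f1_counts):
        ho_obs, he_obs, _, _ = heterozygosity(f1_counts)
        assert he_obs == pytest.approx(14 / 30)
        assert ho_obs == pytest.approx(16 / 30)

    def test_half_frequency_maximum(self):
        g = GenotypeCounts("l", "x", 25, 50, 25)
        *_, het_exp = heterozygosity(g)
        assert het_exp == pytest.approx(0.5)


class TestEffectiveAlleles:
    def test_truncation_f1(self):
        # 1/0.5392 = 1.8546 truncates to 1.85 (not rounded to 1.86)
        assert effective_alleles(0.64, 0.36, "truncate2") == 1.85

    def test_truncation_pooled(self):
        assert effective_alleles(0.57, 0.43, "truncate2") == 1.96

    def test_maximum_at_half(self):
        assert effective_alleles(0.5, 0.5) == pytest.approx(2.0)


class TestPic:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 0.375), (1.0, 0.0), (0.48, 0.37459968)],
    )
    def test_values(self, p, expected):
        assert pic_botstein(p, 1 - p) == pytest.approx(expected)


class TestHweChisq:
    def test_sth_statistic_and_pval(self, sth_counts):
        x2, pval = hwe_chisq(sth_counts, "paper_rounded", df=2)
        assert x2 == pytest.approx(0.03698, abs=1e-4)
        assert round(x2, 2) == 0.04 and round(pval, 2) == 0.98

    def test_f1_statistic(self, f1_counts):
        x2, pval = hwe_chisq(f1_counts, "paper_rounded", df=2)
        assert round(x2, 2) == 0.01 and round(pval, 2) == 0.99

    def test_perfect_hwe_zero(self):
        x2, pval = hwe_chisq(GenotypeCounts("l", "x", 25, 50, 25))
        assert x2 == pytest.approx(0.0) and pval == pytest.approx(1.0)

    def test_monomorphic_with_contradicting_observation(self):
        # expected count 0 for the absent allele's genotypes, but observed > 0
        g = GenotypeCounts("l", "x", 10, 0, 1)
        p, _ = allele_freqs(g, "paper_rounded")
        if p == 1.0:
            x2, pval = hwe_chisq(g, "paper_rounded")
            assert math.isinf(x2) and pval == 0.0

    def test_df1_type_one_error_calibrated(self):
        """Exact-convention df=1 test rejects about alpha under true HWE."""
        from imf.synthetic_data import SimConfig, simulate_genotypes

        rejections = 0
        n_reps = 2000
        for i in range(n_reps):
            g = simulate_genotypes(SimConfig(seed=i, allele_freq=0.48, cohort_n=25))
            if g.n_aa + g.n_ab == 0 or g.n_bb + g.n_ab == 0:
                continue  # monomorphic draw: test undefined
            _, pval = hwe_chisq(g, "exact", df=1)
            rejections += pval < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


@given(
    st.tuples(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    ).filter(lambda t: sum(t) > 0)
)
@settings(max_examples=300, derandomize=True)
def test_invariant_chain_random_counts(counts):
    """PIC <= expected het <= 0.5 and 1 <= Ne <= 2 for any biallelic input."""
    g = GenotypeCounts("l", "x", *counts)
    p, q = allele_freqs(g)
    *_, het_exp = heterozygosity(g)
    ne = effective_alleles(p, q)
    assert pic_botstein(p, q) <= het_exp + 1e-12
    assert het_exp <= 0.5 + 1e-12
    assert 1.0 - 1e-12 <= ne <= 2.0 + 1e-12
    x2, _ = hwe_chisq(g)
    assert x2 >= 0.0


class TestTableReport:
    def test_reproduces_published_diversity_table(self):
        """Golden check of every reproducible printed cell (paper_rounded, df=2)."""
        report = table_report(load_table1_fixture(), convention="paper_rounded", df=2)
        rows = report.set_index("population")
        assert list(rows.index) == ["STH", "SFK x STH", "All"]
        assert rows.loc["STH", ["p", "q", "het_exp", "Ne", "X2", "P"]].tolist() == [
            0.48, 0.52, 0.50, 1.99, 0.04, 0.98,
        ]
        assert rows.loc["SFK x STH", ["p", "q", "he_obs", "ho_obs", "Ne", "X2", "P"]].tolist() == [
            0.64, 0.36, 0.47, 0.53, 1.85, 0.01, 0.99,
        ]
        assert rows.loc["All", ["p", "q", "Ne", "X2", "P"]].tolist() == [
            0.57, 0.43, 1.96, 0.10, 0.95,
        ]
        assert (rows[["n_AA", "n_AB", "n_BB"]].loc["All"] == [18, 26, 11]).all()

    def test_single_population_no_pooled_row(self, sth_counts):
        report = table_report([sth_counts])
        assert len(report) == 1

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            table_report([])


def test_diversity_stats_bundle(f1_counts):
    s = diversity_stats(f1_counts, "paper_rounded", df=2)
    assert isinstance(s, DiversityStats)
    assert s.p + s.q == pytest.approx(1.0)
    assert sum(s.geno_freqs) == pytest.approx(1.0)
    assert s.het_exp == pytest.approx(1.0 - s.hom_exp)
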