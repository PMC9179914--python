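"""QC cascade: missingness, inflection suggestion, MAF, exact HWE, X subset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from conftest import genotypes_from_codes, make_samples, make_two_breed_samples
from sweepscan.data import MISSING, GenotypeMatrix, SampleTable
from sweepscan.qc import (
    MissingnessCurve,
    apply_snp_filters,
    filter_by_missingness,
    hwe_exact_test,
    minor_allele_frequency,
    missingness_profile,
    subset_for_chrX,
    suggest_inflection_cutoff,
)


class TestMissingness:
    def test_complete_matrix_excludes_nothing(self):
        g = genotypes_from_codes(np.ones((4, 5), dtype=int))
        curve = missingness_profile(g, "samples")
        assert (curve.n_excluded[1:] == 0).all()

    def test_half_missing_sample_drops_at_50(self):
        codes = np.ones((3, 4), dtype=int)
        codes[0, :2] = MISSING
        curve = missingness_profile(genotypes_from_codes(codes), "samples")
        assert curve.n_excluded[curve.thresholds == 49][0] == 1
        assert curve.n_excluded[curve.thresholds == 50][0] == 0

    def test_all_missing_degenerate(self):
        g = genotypes_from_codes(np.full((3, 4), MISSING))
        curve = missingness_profile(g, "loci")
        assert (curve.n_excluded[curve.thresholds < 100] == 4).all()

    def test_curve_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            MissingnessCurve("loci", np.arange(3.0), np.array([0, 1, 0]))


class TestInflection:
    def _curve(self, y, axis="samples"):
        return MissingnessCurve(axis, np.arange(len(y), dtype=float), np.asarray(y))

    def test_single_sharp_knee(self):
        # steep drop until 30%, linear afterwards
        y = np.concatenate([1000 - 30 * np.arange(31), [100 - k for k in range(70)]])
        y = np.minimum.accumulate(y)
        assert suggest_inflection_cutoff(self._curve(y)) == 30

    def test_linear_curve_returns_default(self):
        y = 100 - np.arange(101)
        assert suggest_inflection_cutoff(self._curve(y, "samples")) == 30
        assert suggest_inflection_cutoff(self._curve(y, "loci")) == 15

    def test_tie_breaks_toward_stringency(self):
        y = np.array([6, 4, 4, 2, 2, 2])  # equal knees at t=1 and t=3
        d2 = y[:-2] - 2 * y[1:-1] + y[2:]
        assert d2[0] == d2.max() and d2[2] == d2.max()
        assert suggest_inflection_cutoff(self._curve(y)) == 1


class TestMissingnessFilter:
    def test_boundary_is_retained(self):
        codes = np.zeros((1, 10), dtype=int)
        codes[0, :3] = MISSING  # exactly 30% missing
        g = genotypes_from_codes(codes)
        assert filter_by_missingness(g, "samples", 0.30).n_samples == 1

    def test_strictly_greater_removed(self):
        codes = np.zeros((2, 10), dtype=int)
        codes[0, :4] = MISSING  # 40%
        g = genotypes_from_codes(codes)
        out = filter_by_missingness(g, "samples", 0.30)
        assert out.n_samples == 1 and out.samples.ids[0] == "s1"

    def test_sequential_filtering_rescues_loci(self):
        # the bad sample drives locus 0 over 15%; removing it first rescues it
        codes = np.zeros((6, 2), dtype=int)
        codes[0, :] = MISSING  # bad sample: 100% missing
        g = genotypes_from_codes(codes)
        direct = np.mean(g.codes[:, 0] == MISSING)
        assert direct > 0.15
        g2 = filter_by_missingness(g, "samples", 0.30)
        g3 = filter_by_missingness(g2, "loci", 0.15)
        assert g3.n_snps == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        codes = rng.choice([0, 1, 2, MISSING], size=(12, 8), p=[0.3, 0.3, 0.2, 0.2])
        g = genotypes_from_codes(codes)
        kept = []
        for t in (0.1, 0.3, 0.5, 0.9):
            try:
                kept.append(filter_by_missingness(g, "loci", t).n_snps)
            except ValueError:
                kept.append(0)
        assert kept == sorted(kept)

    def test_everything_filtered_is_error(self):
        g = genotypes_from_codes(np.full((2, 2), MISSING))
        with pytest.raises(ValueError):
            filter_by_missingness(g, "samples", 0.5)


class TestMAF:
    def test_counting(self):
        g = genotypes_from_codes(np.array([[0], [0], [1], [1]]))
        assert minor_allele_frequency(g, 0) == pytest.approx(0.25)

    def test_monomorphic_zero(self):
        g = genotypes_from_codes(np.zeros((4, 1), dtype=int))
        assert minor_allele_frequency(g, 0) == 0.0

    def test_folding(self):
        g = genotypes_from_codes(np.array([[2], [2], [2], [0]]))
        assert minor_allele_frequency(g, 0) == pytest.approx(0.25)

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_orientation_invariance(self, codes):
        codes = np.asarray(codes)[:, None]
        g = genotypes_from_codes(codes, samples=make_samples(len(codes)))
        gf = genotypes_from_codes(2 - codes, samples=make_samples(len(codes)))
        assert minor_allele_frequency(g, 0) == pytest.approx(
            minor_allele_frequency(gf, 0)
        )


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact HWE p: enumerate all genotype configurations with
    the observed allele counts and sum those no more probable than observed."""
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * n_bb

    def log_prob(h):
        # P(het = h | n, nb) under random mating conditioning on allele counts
        bb = (nb - h) // 2
        aa = n - h - bb
        return (
            gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            + h * np.log(2) + gammaln(nb + 1) + gammaln(2 * n - nb + 1)
            - gammaln(2 * n + 1)
        )

    hs = [h for h in range(nb % 2, min(nb, 2 * n - nb) + 1, 2)]
    probs = {h: np.exp(log_prob(h)) for h in hs}
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)) / total


class TestHWE:
    def test_equilibrium_counts(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-10

    def test_monomorphic(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(
        st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)).filter(
            lambda t: 1 <= sum(t) <= 20
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, counts):
        aa, ab, bb = counts
        assert hwe_exact_test(aa, ab, bb) == pytest.approx(
            hwe_enumeration_oracle(aa, ab, bb), abs=1e-9
        )


class TestSNPFilters:
    def _two_breed_genotypes(self, codes):
        codes = np.asarray(codes)
        samples = make_two_breed_samples(codes.shape[0] // 2)
        return genotypes_from_codes(codes, samples=samples)

    def test_low_maf_excluded(self):
        # pooled MAF = 2/24 ~ 0.083 < 0.10
        codes = np.zeros((12, 1), dtype=int)
        codes[0, 0] = codes[6, 0] = 1
        g = self._two_breed_genotypes(codes)
        out, report = apply_snp_filters(g)
        assert out.n_snps == 0
        assert report.df["fail_reason"].iloc[0] == "maf"

    def test_common_equilibrium_snp_retained(self):
        rng = np.random.default_rng(1)
        codes = rng.binomial(2, 0.4, size=(20, 1))
        g = self._two_breed_genotypes(codes)
        out, report = apply_snp_filters(g)
        assert out.n_snps == 1 and report.df["pass"].iloc[0]

    def test_het_excess_in_one_breed_excluded(self):
        codes = np.concatenate(
            [np.ones((20, 1), dtype=int), np.zeros((20, 1), dtype=int)]
        )
        codes[20:30, 0] = 2  # second breed in equilibrium-ish mix
        g = self._two_breed_genotypes(codes)
        # breed 1 all het: exact p = enumeration << 0.0002
        out, report = apply_snp_filters(g)
        assert report.df["fail_reason"].iloc[0] == "hwe"
        assert out.n_snps == 0

    def test_report_evaluates_both_criteria(self):
        codes = np.zeros((12, 1), dtype=int)
        g = self._two_breed_genotypes(codes)
        _, report = apply_snp_filters(g)
        assert {"maf", "hwe_p_fat_tail", "hwe_p_thin_tail"} <= set(report.df.columns)


class TestChrXSubset:
    def test_study_design_counts(self):
        rows = []
        for breed in ("fat_tail", "thin_tail"):
            for i in range(45):
                rows.append(
                    {"id": f"{breed}{i}", "breed": breed,
                     "sex": "F" if i < 37 else "M"}
                )
        samples = SampleTable(pd.DataFrame(rows))
        g = genotypes_from_codes(np.zeros((90, 2), dtype=int), samples=samples)
        sub, sub_samples = subset_for_chrX(g)
        assert len(sub_samples) == 74
        assert (sub_samples.df.groupby("breed").size() == 37).all()

    def test_all_female_unchanged(self):
        samples = make_two_breed_samples(3)
        g = genotypes_from_codes(np.zeros((6, 2), dtype=int), samples=samples)
        sub, _ = subset_for_chrX(g)
        assert sub.n_samples == 6

    def test_unknown_sex_dropped(self):
        samples = make_two_breed_samples(2)
        samples.df.loc[0, "sex"] = "U"
        g = genotypes_from_codes(np.zeros((4, 2), dtype=int), samples=samples)
        sub, _ = subset_for_chrX(g)
        assert sub.n_samples == 3

    def test_no_females_is_error(self):
        samples = make_two_breed_samples(2)
        samples.df.loc[samples.df["breed"] == "fat_tail", "sex"] = "M"
        g = genotypes_from_codes(np.zeros((4, 2), dtype=int), samples=samples)
        with pytest.raises(ValueError):
            subset_for_chrX(g)
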