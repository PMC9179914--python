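"""EHH decay, iHH integration, iHS standardization, XP-EHH, pairwise r2."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.haplo import (
    EHHProfile,
    ehh_profile,
    integrate_ehh,
    ihs_scan,
    pairwise_r2,
    standardize_ihs,
    standardize_xpehh,
    unstandardized_ihs,
    windowed_abs_ihs,
    xpehh_raw,
)


def brute_force_ehh(H, rows, core, j):
    """Oracle: all-pairs identity count over the closed interval core..j."""
    lo, hi = min(core, j), max(core, j)
    segs = [tuple(H[r, lo : hi + 1]) for r in rows]
    n = len(rows)
    return sum(c * (c - 1) / 2 for c in Counter(segs).values()) / (n * (n - 1) / 2)


class TestEHH:
    def test_core_identity_is_one(self):
        H = np.array([[1, 0, 1], [1, 1, 0], [0, 0, 1]])
        prof = ehh_profile(H, 1, "0")
        assert prof.ehh_right[0] == 1.0 and prof.ehh_left[0] == 1.0

    def test_two_two_split_gives_one_third(self):
        # 4 carriers of allele 0 at the core split 2/2 at the next SNP
        H = np.array([[0, 0], [0, 0], [0, 1], [0, 1]])
        prof = ehh_profile(H, 0, "0")
        assert prof.ehh_right[1] == pytest.approx(1 / 3)  # (1+1)/C(4,2)

    def test_identical_carriers_stay_at_one(self):
        H = np.tile([1, 0, 1, 1, 0], (5, 1))
        prof = ehh_profile(H, 2, "1")
        assert (prof.ehh_right == 1).all() and (prof.ehh_left == 1).all()

    def test_fewer_than_two_carriers_rejected(self):
        H = np.array([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            ehh_profile(H, 0, "1")

    def test_monotone_non_increasing_enforced(self):
        with pytest.raises(AssertionError):
            EHHProfile(0, "all", 4, np.arange(3), np.arange(3),
                       np.array([1.0, 0.5, 0.6]), np.arange(1), np.array([1.0]))

    @given(st.integers(0, 2**40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_pair_counting(self, bits):
        rng = np.random.default_rng(bits)
        n_hap = int(rng.integers(3, 13))
        H = rng.integers(0, 2, size=(n_hap, 10))
        core = int(rng.integers(0, 10))
        for allele in ("0", "1", "all"):
            if allele == "all":
                rows = np.arange(n_hap)
            else:
                rows = np.flatnonzero(H[:, core] == int(allele))
                if len(rows) < 2:
                    continue
            prof = ehh_profile(H, core, allele)
            for k, j in enumerate(prof.idx_right):
                assert prof.ehh_right[k] == pytest.approx(
                    brute_force_ehh(H, rows, core, j)
                )
            for k, j in enumerate(prof.idx_left):
                assert prof.ehh_left[k] == pytest.approx(
                    brute_force_ehh(H, rows, core, j)
                )


def profile_from_values(positions, ehh_right, ehh_left=None, core=0):
    """Hand-built profile helper; positions indexed by SNP."""
    positions = np.asarray(positions)
    idx_right = np.arange(core, core + len(ehh_right))
    if ehh_left is None:
        idx_left = np.array([core])
        ehh_left = np.array([1.0])
    else:
        idx_left = np.arange(core, core - len(ehh_left), -1)
    return EHHProfile(core, "derived", 4, positions,
                      idx_right, np.asarray(ehh_right, float),
                      idx_left, np.asarray(ehh_left, float))


class TestIntegrateEHH:
    def test_plateau_then_drop(self):
        # EHH 1 over 10,000 bp then 0 at the next SNP 1,000 bp further;
        # crossing interpolated at (1 - 0.05)/1 of the gap
        prof = profile_from_values(
            [0, 10_000, 11_000], [1.0, 1.0, 0.0]
        )
        res = integrate_ehh(prof, cutoff=0.05)
        sliver = 0.95 * 1000 * (1 + 0.05) / 2
        assert res.area == pytest.approx(10_000 + sliver)
        # the empty left side sits at the region edge, hence the flag
        assert res.edge_truncated

    def test_immediate_drop_both_sides(self):
        prof = profile_from_values(
            [1000, 2000, 3000],
            ehh_right=[1.0, 0.0],
            ehh_left=[1.0, 0.0],
            core=1,
        )
        res = integrate_ehh(prof, cutoff=0.05)
        # each side contributes the interpolated sliver of its first segment
        assert res.area == pytest.approx(2 * 0.95 * 1000 * 1.05 / 2)

    def test_symmetric_profile_equal_areas(self):
        pos = [0, 100, 200, 300, 400]
        right = [1.0, 0.6, 0.01]
        prof_sym = profile_from_values(pos, right, ehh_left=right, core=2)
        prof_half = profile_from_values(pos, right, ehh_left=None, core=2)
        a_sym = integrate_ehh(prof_sym).area
        a_half = integrate_ehh(prof_half).area
        assert a_sym == pytest.approx(2 * a_half)

    def test_single_point_zero_area_flagged(self):
        prof = profile_from_values([0], [1.0])
        res = integrate_ehh(prof)
        assert res.area == 0.0 and res.edge_truncated

    def test_never_crossing_flags_edge(self):
        prof = profile_from_values([0, 500, 1000], [1.0, 0.9, 0.8])
        res = integrate_ehh(prof)
        assert res.edge_truncated


class TestUIHS:
    def test_equal_areas_give_zero(self):
        assert unstandardized_ihs(5.0, 5.0) == 0.0

    def test_closed_form(self):
        assert unstandardized_ihs(2.0, 1.0) == pytest.approx(np.log(2))

    def test_antisymmetric(self):
        assert unstandardized_ihs(3.0, 7.0) == pytest.approx(
            -unstandardized_ihs(7.0, 3.0)
        )

    def test_zero_area_is_na(self):
        assert np.isnan(unstandardized_ihs(0.0, 1.0))

    def test_ancestral_relabel_negates(self, sweep_dataset):
        haps = sweep_dataset["haps"].subset_breed("fat_tail")
        rec = ihs_scan(haps)
        j = int(rec["uihs"].first_valid_index())
        flipped = haps.snp_map.df.copy()
        a, b, anc = flipped.loc[j, ["allele_a", "allele_b", "ancestral"]]
        flipped.loc[j, "ancestral"] = b if anc == a else a
        from sweepscan.data import HaplotypeSet, SNPMap

        haps2 = HaplotypeSet(haps.haps, SNPMap(flipped), haps.samples)
        rec2 = ihs_scan(haps2)
        assert rec2["uihs"][j] == pytest.approx(-rec["uihs"][j])


class TestStandardizeIHS:
    def test_pair_in_one_bin(self):
        rec = pd.DataFrame({"uihs": [-1.0, 1.0], "daf": [0.5, 0.5]})
        ihs, _ = standardize_ihs(rec, n_bins=1)
        assert sorted(ihs.tolist()) == pytest.approx(
            [-np.sqrt(0.5), np.sqrt(0.5)]
        ) or sorted(ihs.tolist()) == pytest.approx([-1.0, 1.0])

    def test_overall_mean_zero(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame(
            {"uihs": rng.normal(size=400), "daf": rng.uniform(0.05, 0.95, 400)}
        )
        ihs, bins = standardize_ihs(rec)
        assert abs(np.nanmean(ihs)) < 1e-9
        assert np.nanvar(ihs) == pytest.approx(1.0, abs=1 / np.sqrt(400) + 0.05)

    def test_single_snp_bin_is_na(self):
        rec = pd.DataFrame({"uihs": [0.7], "daf": [0.5]})
        ihs, bins = standardize_ihs(rec)
        assert np.isnan(ihs[0])

    def test_x_standardized_separately(self):
        rng = np.random.default_rng(6)
        n = 200
        rec = pd.DataFrame(
            {
                "uihs": np.r_[rng.normal(0, 1, n), rng.normal(3, 2, n)],
                "daf": np.tile(rng.uniform(0.05, 0.95, n), 2),
            }
        )
        flags = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        ihs, _ = standardize_ihs(rec, x_flag=flags)
        assert abs(np.nanmean(ihs[:n])) < 1e-9
        assert abs(np.nanmean(ihs[n:])) < 1e-9


class TestWindowedAbsIHS:
    def test_constant_magnitude(self):
        out = windowed_abs_ihs(np.full(15, 2.0), window=10)
        assert np.nanmax(out) == pytest.approx(2.0)
        assert np.isnan(out[:5]).all()  # center-right assignment

    def test_alternating_signs(self):
        out = windowed_abs_ihs(np.array([1.0, -1.0] * 10), window=10)
        assert np.nanmax(out) == pytest.approx(1.0)

    def test_na_members_dropped(self):
        v = np.r_[np.ones(7), [np.nan] * 3, np.ones(5)]
        out = windowed_abs_ihs(v, window=10)
        assert np.nanmax(out) == pytest.approx(1.0)

    def test_short_chromosome_all_na(self):
        out = windowed_abs_ihs(np.ones(5), window=10)
        assert np.isnan(out).all()


class TestXPEHH:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, size=(20, 9))
        pos = 1000 * np.arange(1, 10)
        from sweepscan.data import SNPMap, SampleTable, HaplotypeSet
        import pandas as pd

        rec = xpehh_raw(H, H.copy(), 4)
        assert rec.raw == pytest.approx(0.0)

    def test_swap_negates(self):
        rng = np.random.default_rng(3)
        Ha = rng.integers(0, 2, size=(16, 9))
        Hb = rng.integers(0, 2, size=(18, 9))
        r1 = xpehh_raw(Ha, Hb, 4)
        r2 = xpehh_raw(Hb, Ha, 4)
        assert r1.raw == pytest.approx(-r2.raw)

    def test_sweep_population_positive(self, sweep_dataset):
        haps = sweep_dataset["haps"]
        core = sweep_dataset["cfg"].sweep.core_index
        rec = xpehh_raw(
            haps.subset_breed("fat_tail"), haps.subset_breed("thin_tail"), core
        )
        assert rec.raw > 0


class TestStandardizeXPEHH:
    def test_pair(self):
        out = standardize_xpehh(np.array([-1.0, 1.0]))
        assert sorted(out.tolist()) == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_mean_zero(self):
        rng = np.random.default_rng(8)
        out = standardize_xpehh(rng.normal(2, 3, 500))
        assert abs(np.nanmean(out)) < 1e-9

    def test_constant_series_all_na(self):
        out = standardize_xpehh(np.full(5, 1.3))
        assert np.isnan(out).all()


class TestPairwiseR2:
    def test_perfect_coupling(self):
        H = np.array([[0, 0]] * 5 + [[1, 1]] * 5)
        assert pairwise_r2(H, 0, 1) == pytest.approx(1.0)

    def test_independence(self):
        H = np.array([[1, 1]] * 25 + [[1, 0]] * 25 + [[0, 1]] * 25 + [[0, 0]] * 25)
        assert pairwise_r2(H, 0, 1) == pytest.approx(0.0)

    def test_partial_ld(self):
        H = np.array([[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40)
        assert pairwise_r2(H, 0, 1) == pytest.approx(0.36)

    def test_monomorphic_is_na(self):
        H = np.array([[0, 0], [0, 1]])
        assert np.isnan(pairwise_r2(H, 0, 1))
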