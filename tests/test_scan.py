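"""xpEHH scan: frequencies, EHHS decay, iES integration, standardisation
and the scan's symmetry properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crestscan import (
    DegenerateDistributionError,
    HapSimConfig,
    HaplotypeMatrix,
    InvalidInputError,
    ScanConfig,
    ehhs_profile,
    integrate_ies,
    joint_maf_filter,
    simulate_haplotypes,
    site_frequencies,
    standardize_and_logp,
    xpehh_scan,
)
from crestscan.scan import EhhsProfile

from conftest import ehhs_pairwise_oracle, full_profile, make_panel, random_panel


class TestSiteFrequencies:
    def test_degenerate_and_symmetric_columns(self):
        H = make_panel([[0, 0], [0, 0], [1, 1], [1, 0]])
        freq, maf = site_frequencies(H)
        assert freq[1] == 0.25 and maf[1] == 0.25
        H0 = make_panel(np.zeros((4, 1)))
        f, m = site_frequencies(H0)
        assert f[0] == 0 and m[0] == 0
        H5 = make_panel([[0], [0], [1], [1]])
        f, m = site_frequencies(H5)
        assert f[0] == 0.5 and m[0] == 0.5

    def test_matches_brute_force_recount(self, rng):
        H = random_panel(rng, n_hap=100, n_sites=50)
        freq, maf = site_frequencies(H)
        for j in range(50):
            f = sum(H.alleles[i, j] for i in range(100)) / 100
            assert freq[j] == pytest.approx(f)
            assert maf[j] == pytest.approx(min(f, 1 - f))

    def test_empty_matrix_rejected(self):
        H = make_panel(np.zeros((4, 1)))
        H.alleles = np.zeros((4, 0), dtype=np.uint8)
        H.positions = np.array([], dtype=np.int64)
        with pytest.raises(InvalidInputError):
            site_frequencies(H)


class TestJointMafFilter:
    def test_boundary_is_strict(self):
        # pooled maf exactly 0.05: 1 derived of 20 pooled haplotypes
        col = np.zeros((10, 1), dtype=np.uint8)
        colb = col.copy()
        colb[0, 0] = 1
        A, B = make_panel(col), make_panel(colb)
        assert joint_maf_filter(A, B, ScanConfig()).size == 0

    def test_monomorphic_all_excluded(self):
        A = make_panel(np.zeros((6, 5)))
        B = make_panel(np.ones((6, 5)) * 0)
        assert joint_maf_filter(A, B).size == 0

    def test_matches_pooled_recount(self, rng):
        A = random_panel(rng, 20, 40)
        B = make_panel(rng.integers(0, 2, (20, 40)), positions=A.positions)
        got = joint_maf_filter(A, B, ScanConfig(maf_threshold=0.1))
        pooled = np.vstack([A.alleles, B.alleles])
        expect = [
            j
            for j in range(40)
            if min(pooled[:, j].mean(), 1 - pooled[:, j].mean()) > 0.1
        ]
        assert got.tolist() == expect

    def test_mismatched_positions_rejected(self, rng):
        A = random_panel(rng, 8, 10)
        B = make_panel(A.alleles, positions=A.positions + 1)
        with pytest.raises(InvalidInputError):
            joint_maf_filter(A, B)


class TestEhhs:
    def test_identical_haplotypes_stay_one(self):
        H = make_panel(np.tile([0, 1, 0], (6, 1)))
        p = ehhs_profile(H, 1)
        assert np.all(p.left_values == 1) and np.all(p.right_values == 1)
        assert p.censored_left and p.censored_right

    def test_four_haplotype_toy(self):
        """Hand enumeration: haplotypes (010),(010),(111),(011), focal
        at the middle site.  Right side: groups {10,10},{11,11} ->
        (1+1)/6; focal homozygosity 6/6; EHHS = 1/3.  Left side: group
        sizes {3,1} -> 3/6 -> EHHS = 1/2."""
        H = make_panel(
            [[0, 1, 0], [0, 1, 0], [1, 1, 1], [0, 1, 1]], positions=[100, 200, 300]
        )
        p = ehhs_profile(H, 1)
        assert p.right_values[0] == 1.0
        assert p.right_values[1] == pytest.approx(1 / 3, abs=1e-12)
        assert p.left_values[1] == pytest.approx(1 / 2, abs=1e-12)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 21))
            L = int(rng.integers(5, 41))
            H = random_panel(rng, n, L)
            focal = int(rng.integers(0, L))
            left, right = ehhs_pairwise_oracle(H, focal)
            p = full_profile(H, focal)
            for got, exp in ((p.left_values, left), (p.right_values, right)):
                k = got.size
                assert np.allclose(got, exp[:k], atol=1e-12)
                assert np.all(exp[k:] == 0.0)

    def test_non_increasing_and_starts_at_one(self, rng):
        H = random_panel(rng, 12, 30)
        p = full_profile(H, 15)
        assert p.left_values[0] == 1.0 and p.right_values[0] == 1.0
        assert np.all(np.diff(p.left_values) <= 1e-12)
        assert np.all(np.diff(p.right_values) <= 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 16), st.integers(3, 25))
    def test_oracle_property(self, seed, n, L):
        rng = np.random.default_rng(seed)
        H = random_panel(rng, n, L)
        focal = int(rng.integers(0, L))
        left, right = ehhs_pairwise_oracle(H, focal)
        p = full_profile(H, focal)
        assert np.allclose(p.right_values, right[: p.right_values.size], atol=1e-12)
        assert np.allclose(p.left_values, left[: p.left_values.size], atol=1e-12)

    def test_gap_censoring(self):
        H = make_panel(
            np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]]),
            positions=[100, 200, 500_000],
        )
        p = ehhs_profile(H, 1, ScanConfig(max_gap_bp=200_000))
        assert p.censored_right  # 499,800 bp gap exceeds the maximum
        assert p.right_values.size == 1

    def test_too_few_haplotypes_rejected(self):
        with pytest.raises(InvalidInputError):
            make_panel([[0, 1], [1, 0]])


class TestIntegrateIes:
    def test_hand_trapezoid(self):
        p = EhhsProfile(
            focal_index=0,
            left_values=np.array([1.0]),
            left_positions=np.array([200]),
            right_values=np.array([1.0, 1 / 3]),
            right_positions=np.array([200, 300]),
            censored_left=True,
            censored_right=False,
        )
        ies, censored = integrate_ies(p, ScanConfig())
        assert ies == pytest.approx((1 + 1 / 3) / 2 * 100, abs=1e-3)  # 66.667
        assert censored

    def test_truncation_stops_after_first_subthreshold_site(self):
        p = EhhsProfile(
            focal_index=0,
            left_values=np.array([1.0]),
            left_positions=np.array([0]),
            right_values=np.array([1.0, 0.5, 0.04, 0.04]),
            right_positions=np.array([0, 100, 200, 300]),
            censored_left=True,
            censored_right=False,
        )
        ies, _ = integrate_ies(p, ScanConfig(ehhs_truncation=0.05))
        assert ies == pytest.approx((1.5 / 2) * 100 + (0.54 / 2) * 100)

    def test_constant_profile_full_span(self, rng):
        H = make_panel(np.tile([0, 1, 0, 1], (6, 1)), positions=[10, 500, 900, 1500])
        p = ehhs_profile(H, 1)
        ies, censored = integrate_ies(p)
        assert ies == pytest.approx(1490.0)
        assert censored

    def test_single_site_profile_zero(self):
        H = make_panel(np.array([[0], [0], [1], [1]]), positions=[42])
        ies, _ = integrate_ies(ehhs_profile(H, 0))
        assert ies == 0.0


class TestStandardize:
    def test_zero_z_gives_zero_logp(self):
        mid = standardize_and_logp(np.array([0.0, 1.0, -1.0]))
        i = np.argmin(np.abs(mid[0]))
        assert mid[1][i] == pytest.approx(0.0, abs=1e-12)

    def test_normal_quantile_example(self):
        """An entry standardised to |z| = 3.2905 has two-sided p 0.001,
        i.e. logp 3.000."""
        zstar = 3.2905
        a = 1.0
        n = 23
        b = a * np.sqrt((n - 1) / (2 * zstar**2) - 1)
        raw = np.concatenate([[a, -a, b, -b], np.zeros(n - 4)])
        z, logp = standardize_and_logp(raw)
        assert z[0] == pytest.approx(zstar, abs=1e-6)
        assert logp[0] == pytest.approx(3.000, abs=1e-3)

    def test_negation_antisymmetry(self, rng):
        raw = rng.normal(size=200)
        z1, p1 = standardize_and_logp(raw)
        z2, p2 = standardize_and_logp(-raw)
        assert np.allclose(z2, -z1)
        assert np.allclose(p2, p1)

    def test_degenerate_and_invalid(self):
        with pytest.raises(DegenerateDistributionError):
            standardize_and_logp(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(InvalidInputError):
            standardize_and_logp(np.array([1.0, np.inf]))

    def test_extreme_z_finite_logp(self):
        raw = np.concatenate([np.zeros(1000), [500.0]])
        z, logp = standardize_and_logp(raw)
        assert np.isfinite(logp).all()
        assert logp[-1] > 100


@pytest.fixture(scope="module")
def small_pair():
    cfg = HapSimConfig(
        n_haplotypes_per_pop=20,
        population_size=100,
        n_sites=400,
        chrom_length=150_000,
        n_generations=15,
        seed=42,
    )
    return simulate_haplotypes(cfg)


class TestXpehhScan:
    def test_identical_panels_degenerate(self, small_pair):
        A, _ = small_pair
        B = HaplotypeMatrix(A.chrom, A.positions, A.alleles.copy(), "copy")
        with pytest.raises(DegenerateDistributionError):
            xpehh_scan(A, B)

    def test_population_swap_antisymmetry(self, small_pair):
        A, B = small_pair
        fwd = xpehh_scan(A, B)
        rev = xpehh_scan(B, A)
        assert len(fwd) == len(rev) > 50
        for f, r in zip(fwd, rev):
            assert f.pos == r.pos
            assert f.xpehh_raw == pytest.approx(-r.xpehh_raw, abs=1e-12)
            assert f.z == pytest.approx(-r.z, abs=1e-9)
            assert f.logp == pytest.approx(r.logp, abs=1e-9)
            assert (f.maf_A, f.maf_B) == (r.maf_B, r.maf_A)

    def test_records_sorted_and_finite(self, small_pair):
        A, B = small_pair
        recs = xpehh_scan(A, B)
        pos = [r.pos for r in recs]
        assert pos == sorted(pos)
        assert all(np.isfinite(r.z) and r.logp >= 0 for r in recs)
        assert all(r.iES_A > 0 and r.iES_B > 0 for r in recs)

    def test_no_surviving_sites_warns_empty(self):
        A = make_panel(np.zeros((6, 5)))
        B = make_panel(np.zeros((6, 5)))
        with pytest.warns(UserWarning):
            assert xpehh_scan(A, B) == []
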