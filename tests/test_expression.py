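"""Expression divergence: normalisation, filtering, the NB Wald test,
Z-profiles and complete-linkage clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crestscan import (
    Contrast,
    CountsMatrix,
    CountsSimConfig,
    InvalidInputError,
    NormalizationError,
    SampleMeta,
    call_degs,
    cluster_profiles,
    collapse_technical_replicates,
    de_contrast,
    low_count_filter,
    make_contrasts,
    simulate_counts,
    size_factors,
    stage_profiles,
)
from crestscan.expression import DEGRecord


def counts(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return CountsMatrix(genes, samples, mat)


def meta_2x2(n_rep=2, n_stage=1):
    """Metadata whose sample ids line up with the ``counts`` helper's
    default column names (species-major, then stage, then replicate)."""
    rows = []
    k = 0
    for sp in "AB":
        for st in range(n_stage):
            for r in range(n_rep):
                rows.append((f"s{k}", sp, st, r))
                k += 1
    return SampleMeta(
        pd.DataFrame(rows, columns=["sample_id", "species", "stage", "replicate"])
    )


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        f = size_factors(counts([[2, 2], [8, 8]]))
        assert np.allclose(f, [1.0, 1.0])

    def test_hand_median_of_ratios(self):
        f = size_factors(counts([[2, 4], [8, 16]]))
        assert f == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_scale_equivariance_and_gene_order_invariance(self, rng):
        """Scaling one sample's column by c moves its factor up by
        c^(1-1/m) and every other factor down by c^(-1/m) (the scaled
        sample also shifts the geometric-mean reference), so factor
        ratios against any other sample change by exactly c."""
        mat = rng.integers(1, 500, (40, 6))
        f = size_factors(counts(mat))
        scaled = mat.astype(float).copy()
        scaled[:, 2] *= 3.0
        f2 = size_factors(CountsMatrix([f"g{i}" for i in range(40)],
                                       [f"s{j}" for j in range(6)], scaled))
        assert f2[2] == pytest.approx(f[2] * 3 ** (5 / 6))
        assert np.allclose(np.delete(f2, 2), np.delete(f, 2) * 3 ** (-1 / 6))
        assert (f2[2] / f2[0]) == pytest.approx(3 * f[2] / f[0])
        perm = rng.permutation(40)
        f3 = size_factors(counts(mat[perm]))
        assert np.allclose(f3, f)

    def test_no_reference_gene_raises(self):
        with pytest.raises(NormalizationError):
            size_factors(counts([[0, 5], [5, 0]]))


class TestLowCountFilter:
    def test_rules(self):
        m = meta_2x2(n_rep=2)
        mat = [
            [0, 0, 0, 0],      # all zero -> removed
            [10, 0, 0, 0],     # one sample at the boundary -> retained
            [9, 9, 9, 9],      # below threshold everywhere -> removed
            [0, 0, 50, 50],    # expressed in B only -> retained under 'both'
        ]
        keep = low_count_filter(counts(mat), m, 10)
        assert keep.tolist() == [False, True, False, True]
        keep_either = low_count_filter(counts(mat), m, 10, mode="either")
        assert keep_either.tolist() == [False, False, False, False]

    def test_mode_validation(self):
        with pytest.raises(InvalidInputError):
            low_count_filter(counts([[1, 1, 1, 1]]), meta_2x2(), mode="bogus")


class TestDeContrast:
    def test_identical_groups_zero_lfc(self, rng):
        base = rng.integers(0, 300, (50, 2))
        mat = np.hstack([base, base])
        m = meta_2x2(n_rep=2)
        recs = de_contrast(counts(mat), np.ones(4), m, make_contrasts(m)[0])
        assert all(r.log2fc == 0 for r in recs)

    def test_all_zero_group_rejected(self):
        m = meta_2x2(n_rep=2)
        mat = [[0, 0, 5, 9], [0, 0, 2, 1]]
        with pytest.raises(InvalidInputError):
            de_contrast(counts(mat), np.ones(4), m, make_contrasts(m)[0])

    def test_planted_fourfold_recovered(self, rng):
        """Genes planted at a true 4-fold difference and high expression
        are recovered at |log2FC| >= 1.5 in >= 90% of cases."""
        n, mean = 200, 256.0
        r_nb = 20.0  # alpha = 0.05
        mu1 = np.full((n, 3), mean)
        mu2 = np.full((n, 3), mean)
        mu2[:100] *= 4.0
        draw = lambda mu: rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        mat = np.hstack([draw(mu1), draw(mu2)])
        m = meta_2x2(n_rep=3)
        recs = de_contrast(counts(mat), np.ones(6), m, make_contrasts(m)[0])
        lfc = np.array([r.log2fc for r in recs])
        assert (np.abs(lfc[:100]) >= 1.5).mean() >= 0.9
        assert np.abs(lfc[100:]).mean() < 0.5

    def test_bh_monotone_in_raw_p(self, rng):
        mat = rng.integers(0, 400, (300, 6))
        m = meta_2x2(n_rep=3)
        recs = de_contrast(counts(mat), np.ones(6), m, make_contrasts(m)[0])
        order = np.argsort([r.pvalue for r in recs])
        padj_sorted = np.array([recs[i].padj for i in order])
        assert np.all(np.diff(padj_sorted) >= -1e-12)


class TestCallDegs:
    def test_boundary_inclusive(self):
        r1 = DEGRecord("g1", "c", log2fc=0.585, pvalue=0.001, padj=0.01)
        r2 = DEGRecord("g2", "c", log2fc=2.0, pvalue=0.01, padj=0.06)
        degs = call_degs([r1, r2])
        assert degs == {"g1"} and r1.is_deg and not r2.is_deg

    def test_union_over_contrasts_matches_predicate_scan(self, rng):
        recs = [
            DEGRecord(f"g{i % 40}", f"c{i % 3}",
                      log2fc=float(rng.normal(0, 1.5)),
                      pvalue=float(rng.uniform()),
                      padj=float(rng.uniform()))
            for i in range(200)
        ]
        degs = call_degs(recs, 0.585, 0.05)
        expect = {r.gene_id for r in recs
                  if abs(r.log2fc) >= 0.585 and r.padj < 0.05}
        assert degs == expect


class TestStageProfiles:
    def test_constant_gene_excluded(self):
        m = meta_2x2(n_rep=2, n_stage=2)
        mat = np.tile([7], (1, 8))
        Z, excluded = stage_profiles(counts(mat), np.ones(8), m)
        assert excluded[0]
        assert np.all(Z.to_numpy() == 0)

    def test_mean_zero_sd_one(self, rng):
        m = meta_2x2(n_rep=2, n_stage=3)
        mat = rng.integers(1, 1000, (30, 12))
        Z, excluded = stage_profiles(counts(mat), np.ones(12), m)
        zz = Z.to_numpy()[~excluded]
        assert np.allclose(zz.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(zz.std(axis=1), 1, atol=1e-9)

    def test_hand_toy(self):
        """2 stages x 2 species, one replicate each: means are the
        normalised counts themselves; Z is direct arithmetic."""
        rows = [("A_0", "A", 0, 0), ("A_1", "A", 1, 0),
                ("B_0", "B", 0, 0), ("B_1", "B", 1, 0)]
        m = SampleMeta(pd.DataFrame(rows, columns=["sample_id", "species",
                                                   "stage", "replicate"]))
        M = CountsMatrix(["g"], ["A_0", "A_1", "B_0", "B_1"],
                         np.array([[10, 20, 30, 40]]))
        Z, _ = stage_profiles(M, np.ones(4), m)
        v = np.array([10, 20, 30, 40], dtype=float)
        expect = (v - v.mean()) / v.std()
        assert np.allclose(Z.to_numpy()[0], expect)
        assert list(Z.columns) == ["A_0", "A_1", "B_0", "B_1"]


class TestClusterProfiles:
    def test_two_far_archetypes_perfect_split(self, rng):
        a = np.tile([2.0, -2.0, 2.0, -2.0], (10, 1))
        b = np.tile([-2.0, 2.0, -2.0, 2.0], (10, 1))
        Z = pd.DataFrame(np.vstack([a, b]) + rng.normal(0, 0.05, (20, 4)),
                         index=[f"g{i}" for i in range(20)])
        clusters = cluster_profiles(Z, 2)
        truth = [0] * 10 + [1] * 10
        labels = np.zeros(20, int)
        for c in clusters:
            for g in c.gene_ids:
                labels[int(g[1:])] = c.cluster_id
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicates_co_clustered(self, rng):
        Z = pd.DataFrame(rng.normal(size=(12, 6)), index=[f"g{i}" for i in range(12)])
        Z.iloc[5] = Z.iloc[2]
        clusters = cluster_profiles(Z, 4)
        for c in clusters:
            assert ("g2" in c.gene_ids) == ("g5" in c.gene_ids)

    def test_row_permutation_invariance(self, rng):
        Z = pd.DataFrame(rng.normal(size=(40, 8)), index=[f"g{i}" for i in range(40)])
        perm = rng.permutation(40)
        c1 = cluster_profiles(Z, 5)
        c2 = cluster_profiles(Z.iloc[perm], 5)
        lab1, lab2 = {}, {}
        for c in c1:
            for g in c.gene_ids:
                lab1[g] = c.cluster_id
        for c in c2:
            for g in c.gene_ids:
                lab2[g] = c.cluster_id
        genes = sorted(lab1)
        assert adjusted_rand_score([lab1[g] for g in genes],
                                   [lab2[g] for g in genes]) == 1.0

    def test_fewer_genes_than_k_rejected(self, rng):
        Z = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(InvalidInputError):
            cluster_profiles(Z, 7)


class TestCollapse:
    def test_technical_replicates_summed(self):
        M = counts([[1, 2, 10], [5, 5, 5]], samples=["a1", "a2", "b"])
        out = collapse_technical_replicates(M, {"a": ["a1", "a2"], "b": ["b"]})
        assert out.sample_ids == ["a", "b"]
        assert out.counts.tolist() == [[3, 10], [10, 5]]
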