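import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from conftest import random_genotypes
from oracles import midrank_rank_sum, pairwise_relative_distance, scalar_loo_D
from poda.errors import ValidationError
from poda.io import GenotypeMatrix, PathwayAnnotation, Pathway, PhenotypeVector
from poda.core import (
    DistanceProfile,
    PermutationEnsemble,
    combine_pathways,
    distinction_score,
    locus_distance,
    pairwise_distance_statistics,
    pathway_rank_sum,
    permutation_null,
    pooled_locus_distances,
    resample_pvalue,
    sample_distance_statistics,
)
from poda.selection import SnpSelection
from poda.simulate import make_annotation_fixture, simulate_xor_gwas


def _profile(D, is_case=None):
    n = len(D)
    return DistanceProfile(
        ["rs"], [f"S{i}" for i in range(n)], np.zeros((n, 1)),
        np.zeros(n), np.zeros(n), np.asarray(D, float), np.ones(n, int),
    )


def _pheno_from(labels):
    labels = np.asarray(labels, bool)
    return PhenotypeVector([f"S{i}" for i in range(len(labels))], labels)


class TestLocusDistance:
    @pytest.mark.parametrize(
        "y,f,g,expected",
        [
            (1.0, 0.2, 0.8, 0.6),
            (0.5, 0.3, 0.3, 0.0),
            (0.0, 0.1, 0.4, -0.3),
        ],
    )
    def test_direct_values(self, y, f, g, expected):
        assert locus_distance(y, f, g) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(
        y=st.sampled_from([0.0, 0.5, 1.0]),
        f=st.floats(0, 1),
        g=st.floats(0, 1),
    )
    def test_bounded_by_unit_interval(self, y, f, g):
        d = locus_distance(y, f, g)
        assert -1 - 1e-12 <= d <= 1 + 1e-12
        # also bounded by the centroid separation itself
        assert abs(d) <= abs(f - g) + 1e-12


class TestSampleDistanceStatistics:
    def test_standardized_mean_direct(self):
        """d = (0.6, 0.2) -> mean 0.4, sd 0.2828, D = 0.4/(sd/sqrt(2)) = 2."""
        d = np.array([0.6, 0.2])
        D = d.mean() / (d.std(ddof=1) / np.sqrt(2))
        assert D == pytest.approx(2.0)
        # the same arithmetic inside the package: craft genotypes realizing it
        # via the scalar identity D = mean/(sd/sqrt(s))
        from poda.core import _standardized_mean

        _, _, Dv, _ = _standardized_mean(d[None, :])
        assert Dv[0] == pytest.approx(2.0)

    def test_identical_samples_give_zero(self):
        values = np.full((10, 4), 0.5)
        gm = GenotypeMatrix([f"S{i}" for i in range(10)], list("abcd"), values)
        ph = _pheno_from([1] * 5 + [0] * 5)
        prof = sample_distance_statistics(gm, ph, list("abcd"))
        np.testing.assert_allclose(prof.D, 0.0)
        np.testing.assert_allclose(prof.d, 0.0)

    def test_label_swap_negates_D(self, small_gwas):
        gm, ph = small_gwas
        swapped = PhenotypeVector(ph.sample_ids, ~ph.is_case)
        D1 = sample_distance_statistics(gm, ph, gm.snp_ids).D
        D2 = sample_distance_statistics(gm, swapped, gm.snp_ids).D
        np.testing.assert_allclose(D1, -D2, atol=1e-10)

    def test_matches_scalar_oracle(self):
        """Vectorized leave-one-out D equals the loop-based scalar formula."""
        gm, ph = random_genotypes(50, 100, seed=7, missing=0.05)
        prof = sample_distance_statistics(gm, ph, gm.snp_ids)
        oracle = np.array(
            [scalar_loo_D(gm.values, ph.is_case, i) for i in range(gm.n_samples)]
        )
        assert np.max(np.abs(prof.D - oracle)) < 1e-10

    def test_leave_one_out_exactness(self, small_gwas):
        """D_i equals the value from physically deleting sample i's genotype
        row from its own class pool before recomputing the MAF centroids."""
        gm, ph = small_gwas
        prof = sample_distance_statistics(gm, ph, gm.snp_ids)
        for i in range(gm.n_samples):
            keep = np.arange(gm.n_samples) != i
            own = ph.is_case[i]
            pool_vals = gm.values[keep]
            pool_case = ph.is_case[keep]
            g = pool_vals[pool_case].mean(axis=0) if own else gm.values[ph.is_case].mean(axis=0)
            f = (
                pool_vals[~pool_case].mean(axis=0)
                if not own
                else gm.values[~ph.is_case].mean(axis=0)
            )
            d = np.abs(gm.values[i] - f) - np.abs(gm.values[i] - g)
            expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert prof.D[i] == pytest.approx(expect, abs=1e-12)

    def test_d_bounds_and_used_loci(self):
        gm, ph = random_genotypes(20, 15, seed=3, missing=0.2)
        prof = sample_distance_statistics(gm, ph, gm.snp_ids)
        finite = prof.d[~np.isnan(prof.d)]
        assert np.all(finite >= -1) and np.all(finite <= 1)
        assert np.all(prof.used_loci <= prof.s)
        assert np.all(np.isfinite(prof.D))

    def test_empty_snp_set_errors(self, small_gwas):
        gm, ph = small_gwas
        with pytest.raises(ValidationError):
            sample_distance_statistics(gm, ph, [])

    def test_all_missing_sample_errors(self, small_gwas):
        gm, ph = small_gwas
        values = gm.values.copy()
        values[0, :2] = np.nan
        gm2 = GenotypeMatrix(gm.sample_ids, gm.snp_ids, values)
        with pytest.raises(ValidationError, match=gm.sample_ids[0]):
            sample_distance_statistics(gm2, ph, gm.snp_ids[:2])


class TestRankSum:
    def test_extremes(self):
        ph = _pheno_from([1, 1, 0, 0])
        assert pathway_rank_sum(_profile([3, 2, 1, 0]), ph) == 7  # maximum
        assert pathway_rank_sum(_profile([0, 1, 2, 3]), ph) == 3  # minimum

    def test_midranks_on_ties(self):
        """Three tied values share midrank 3: case D {1,1} + control {1,0}."""
        ph = _pheno_from([1, 1, 0, 0])
        assert pathway_rank_sum(_profile([1, 1, 1, 0]), ph) == 6

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 15))
            D = rng.integers(0, 4, n).astype(float)  # heavy ties
            n1 = int(rng.integers(2, n - 2))
            labels = np.zeros(n, bool)
            labels[rng.choice(n, n1, replace=False)] = True
            ph = _pheno_from(labels)
            assert pathway_rank_sum(_profile(D), ph) == midrank_rank_sum(D, labels)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=5, max_size=20))
    def test_case_control_ranks_partition(self, dvals):
        """W_cases + W_controls = N(N+1)/2 and W stays in its combinatorial range."""
        D = np.array(dvals, float)
        n = len(D)
        labels = np.zeros(n, bool)
        labels[: n // 2] = True
        ph = _pheno_from(labels)
        inv = _pheno_from(~labels)
        w1 = pathway_rank_sum(_profile(D), ph)
        w0 = pathway_rank_sum(_profile(D), inv)
        assert w1 + w0 == pytest.approx(n * (n + 1) / 2)
        n1 = labels.sum()
        assert n1 * (n1 + 1) / 2 <= w1 <= n1 * (n1 + 1) / 2 + n1 * (n - n1)

    def test_rank_invariance_under_shift(self, small_gwas):
        gm, ph = small_gwas
        D = sample_distance_statistics(gm, ph, gm.snp_ids).D
        assert pathway_rank_sum(_profile(D), ph) == pathway_rank_sum(_profile(D + 7.5), ph)


class TestPermutationNull:
    def _setup(self):
        gm, ph = random_genotypes(40, 10, seed=5)
        ann = make_annotation_fixture(2, 5, 1, snp_ids=gm.snp_ids)
        return gm, ph, ann

    def test_deterministic_for_fixed_seed(self):
        gm, ph, ann = self._setup()
        e1 = permutation_null(gm, ph, ann, "PW_001", n_perm=10, seed=123)
        e2 = permutation_null(gm, ph, ann, "PW_001", n_perm=10, seed=123)
        np.testing.assert_array_equal(e1.w_values, e2.w_values)

    def test_null_mean_matches_closed_form(self):
        """Ensemble mean of W approximates n1(N+1)/2 on label-independent data."""
        gm, ph = random_genotypes(60, 8, seed=9)
        ann = make_annotation_fixture(1, 8, 1, snp_ids=gm.snp_ids)
        ens = permutation_null(gm, ph, ann, "PW_001", n_perm=200, seed=4)
        n1, N = ph.n_cases, gm.n_samples
        expect = n1 * (N + 1) / 2
        assert ens.mean() == pytest.approx(expect, rel=0.02)

    def test_class_counts_preserved(self):
        gm, ph, ann = self._setup()
        ens = permutation_null(gm, ph, ann, "PW_001", n_perm=5, seed=0)
        assert ens.label_matrix.sum(axis=1).tolist() == [ph.n_cases] * 5

    def test_permutations_reselect_snps(self):
        """A gene whose two SNPs' association ordering depends on the labels
        must see the alternate SNP chosen in some permutations."""
        rng = np.random.default_rng(0)
        n = 24
        labels = np.zeros(n, bool)
        labels[:12] = True
        snp_a = labels.astype(float)  # perfect under true labels
        alt = rng.permutation(labels)
        snp_b = alt.astype(float)  # perfect under a permuted labeling
        filler = rng.binomial(2, 0.3, size=(n, 2)) / 2.0
        gm = GenotypeMatrix(
            [f"S{i}" for i in range(n)],
            ["snpA", "snpB", "f1", "f2"],
            np.column_stack([snp_a, snp_b, filler]),
        )
        ph = _pheno_from(labels)
        ann = PathwayAnnotation(
            pathways={"pw": Pathway("pw", "pw", "x", ["G1", "G2", "G3"])},
            gene_snps={"G1": ["snpA", "snpB"], "G2": ["f1"], "G3": ["f2"]},
        )
        ens = permutation_null(gm, ph, ann, "pw", n_perm=40, seed=11)
        picks = {s[0] for s in ens.selected_sets}
        assert picks == {"snpA", "snpB"}

    def test_too_few_permutations(self):
        gm, ph, ann = self._setup()
        with pytest.raises(ValidationError):
            permutation_null(gm, ph, ann, "PW_001", n_perm=1, seed=0)


class TestDistinctionScore:
    def test_zero_at_ensemble_mean(self):
        ens = PermutationEnsemble(4, 0, np.array([48.0, 50.0, 52.0, 50.0]))
        assert distinction_score(50.0, ens) == pytest.approx(0.0)

    def test_direct_value(self):
        w = np.array([45.0, 50.0, 55.0])
        ens = PermutationEnsemble(3, 0, w)
        assert distinction_score(60.0, ens) == pytest.approx((60 - 50) / w.std(ddof=1))

    def test_zero_spread_errors(self):
        ens = PermutationEnsemble(3, 0, np.array([50.0, 50.0, 50.0]))
        with pytest.raises(ValidationError):
            distinction_score(60.0, ens)


class TestResampling:
    def _selection(self, gm, s=4):
        return SnpSelection("pw", [(f"G{j}", gm.snp_ids[j], 0.5) for j in range(s)], gm.snp_ids)

    def test_add_one_estimator_bounds(self):
        gm, ph = random_genotypes(40, 12, seed=13)
        sel = self._selection(gm)
        p = resample_pvalue(gm, ph, sel, n_resample=19, n_perm=20, seed=3)
        assert 1 / 20 <= p <= 1.0

    def test_huge_true_ds_gives_minimum_p(self):
        gm, ph = random_genotypes(40, 12, seed=13)
        sel = self._selection(gm)
        p = resample_pvalue(gm, ph, sel, n_resample=19, n_perm=20, seed=3, true_ds=1e9)
        assert p == pytest.approx(1 / 20)

    def test_tiny_true_ds_gives_one(self):
        gm, ph = random_genotypes(40, 12, seed=13)
        sel = self._selection(gm)
        p = resample_pvalue(gm, ph, sel, n_resample=19, n_perm=20, seed=3, true_ds=-1e9)
        assert p == 1.0

    def test_pool_smaller_than_pathway_errors(self):
        gm, ph = random_genotypes(20, 6, seed=1)
        sel = SnpSelection("pw", [(f"G{j}", gm.snp_ids[j], 0.5) for j in range(6)],
                           gm.snp_ids[:3])
        with pytest.raises(ValidationError):
            resample_pvalue(gm, ph, sel, n_resample=9, n_perm=5, seed=0, true_ds=0.0)

    def test_deterministic(self):
        gm, ph = random_genotypes(30, 10, seed=2)
        sel = self._selection(gm)
        p1 = resample_pvalue(gm, ph, sel, n_resample=49, n_perm=10, seed=77, true_ds=0.5)
        p2 = resample_pvalue(gm, ph, sel, n_resample=49, n_perm=10, seed=77, true_ds=0.5)
        assert p1 == p2


class TestCombinePathways:
    def test_union_deduplicates(self):
        gm, ph = random_genotypes(30, 10, seed=21)
        sels = {
            "p1": SnpSelection("p1", [("G1", "rs0000", 0.1), ("G2", "rs0001", 0.2),
                                      ("G3", "rs0002", 0.3)], gm.snp_ids),
            "p2": SnpSelection("p2", [("G2", "rs0001", 0.2), ("G3", "rs0002", 0.3),
                                      ("G4", "rs0003", 0.4)], gm.snp_ids),
        }
        union, result, profile = combine_pathways(gm, ph, sels, ["p1", "p2"],
                                                  n_perm=10, n_resample=19, seed=0)
        assert union == ["rs0000", "rs0001", "rs0002", "rs0003"]
        assert result.s == 4

    def test_union_statistics_match_direct_computation(self):
        gm, ph = random_genotypes(30, 10, seed=22)
        sels = {
            "p1": SnpSelection("p1", [("G1", "rs0000", 0.1), ("G2", "rs0004", 0.2)], gm.snp_ids),
            "p2": SnpSelection("p2", [("G5", "rs0005", 0.2), ("G6", "rs0006", 0.3)], gm.snp_ids),
        }
        union, result, profile = combine_pathways(gm, ph, sels, ["p1", "p2"],
                                                  n_perm=10, n_resample=19, seed=0)
        direct = sample_distance_statistics(gm, ph, union)
        np.testing.assert_allclose(profile.D, direct.D)
        assert result.W == pathway_rank_sum(direct, ph)


class TestPairwiseVariant:
    def test_identical_samples_zero(self):
        values = np.full((8, 3), 0.5)
        gm = GenotypeMatrix([f"S{i}" for i in range(8)], list("abc"), values)
        ph = _pheno_from([1] * 4 + [0] * 4)
        stat = pairwise_distance_statistics(gm, ph, list("abc"))
        np.testing.assert_allclose(stat, 0.0, atol=1e-12)

    def test_matches_brute_force(self):
        gm, ph = random_genotypes(14, 6, seed=8, missing=0.1)
        for metric in ("euclidean", "manhattan"):
            stat = pairwise_distance_statistics(gm, ph, gm.snp_ids, metric=metric)
            oracle = pairwise_relative_distance(gm.values, ph.is_case, metric)
            np.testing.assert_allclose(stat, oracle, atol=1e-12)

    def test_two_separated_clusters(self):
        """Cases clustered at hom-minor, controls at hom-major: every case
        statistic positive, every control negative."""
        values = np.array(
            [[1, 1, 1], [1, 1, 0.5], [1, 0.5, 1], [0, 0, 0], [0, 0, 0.5], [0, 0.5, 0]],
            dtype=float,
        )
        gm = GenotypeMatrix([f"S{i}" for i in range(6)], list("abc"), values)
        ph = _pheno_from([1, 1, 1, 0, 0, 0])
        stat = pairwise_distance_statistics(gm, ph, list("abc"))
        assert np.all(stat[ph.is_case] > 0)
        assert np.all(stat[~ph.is_case] < 0)

    def test_xor_separated_by_pairwise_but_not_centroids(self):
        """The marginal-matched two-locus configuration: centroid distances
        vanish identically while pairwise distances split the classes."""
        gm, ph = simulate_xor_gwas(40, seed=2)
        d = pooled_locus_distances(gm, ph, ["XOR_1", "XOR_2"])
        contrast = np.abs(d[ph.is_case].mean(axis=0) - d[~ph.is_case].mean(axis=0))
        assert np.all(contrast < 1e-12)
        stat = pairwise_distance_statistics(gm, ph, gm.snp_ids)
        p = mannwhitneyu(stat[ph.is_case], stat[~ph.is_case], alternative="greater")[1]
        assert p < 1e-4
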