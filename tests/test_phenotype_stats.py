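import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from clonoreact import (
    CountsMatrix,
    UndefinedStatisticError,
    ValidationError,
    bh_adjust,
    exact_rank_sum,
    exact_signed_rank,
    fpm_normalize,
    normalize_cells,
    pseudobulk,
    strip_tcr_genes,
    wilcoxon_de,
)
from clonoreact.phenotype_stats import PseudobulkMatrix, pseudobulk_rank_de
from clonoreact.synth import simulate_counts


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: independent of the
    implementation under test."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        k = n - rank_from_top  # 1-based rank in ascending order
        prev = min(prev, p[i] * n / k)
        adj[i] = prev
    return np.minimum(adj, 1.0)


class TestStripTcrGenes:
    def test_prefix_rule(self):
        assert strip_tcr_genes(["TRBV7-2", "CD8A", "TRAJ23"]) == ["CD8A"]

    def test_non_tcr_untouched(self):
        assert strip_tcr_genes(["IKZF2", "KIR2DL1"]) == ["IKZF2", "KIR2DL1"]

    def test_empty(self):
        assert strip_tcr_genes([]) == []


class TestNormalizeCells:
    def matrix(self, arr):
        arr = np.asarray(arr)
        return CountsMatrix(
            gene_ids=[f"G{i}" for i in range(arr.shape[0])],
            barcodes=[f"B{j}" for j in range(arr.shape[1])],
            values=sp.csr_matrix(arr),
        )

    def test_matches_hand_formula(self):
        arr = np.array([[0, 2, 5], [1, 0, 3], [4, 6, 0]])
        norm = normalize_cells(self.matrix(arr), scale=100.0)
        lib = arr.sum(axis=0)
        expected = np.log1p(arr * 100.0 / lib)
        np.testing.assert_allclose(norm, expected, rtol=1e-12)
        assert norm[0, 0] == 0.0  # zero count stays zero

    def test_count_equal_library_identity(self):
        # single-gene cell: count == library size, scale == library size
        arr = np.array([[5]])
        norm = normalize_cells(self.matrix(arr), scale=5.0)
        assert norm[0, 0] == pytest.approx(np.log(1 + 5.0))

    def test_zero_library_size_names_barcode(self):
        with pytest.raises(ValidationError, match="B1"):
            normalize_cells(self.matrix(np.array([[1, 0], [2, 0]])))


class TestWilcoxonDE:
    def test_three_vs_three_exact_p(self):
        norm = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        labels = ["a", "a", "a", "b", "b", "b"]
        (res,) = wilcoxon_de(norm, ["G1"], labels, "a", "b", min_pct=0.0)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=30)
        norm = np.stack([np.concatenate([vals, vals])])
        labels = ["a"] * 30 + ["b"] * 30
        (res,) = wilcoxon_de(norm, ["G1"], labels, "a", "b", min_pct=0.0)
        assert res.p_value > 0.95
        assert res.avg_log2fc == pytest.approx(0.0, abs=1e-12)
        assert not res.significant_up and not res.significant_down

    def test_min_pct_filter(self):
        norm = np.zeros((2, 40))
        norm[0, :2] = 1.0  # expressed in 10% of group a only
        labels = ["a"] * 20 + ["b"] * 20
        res = wilcoxon_de(norm, ["G1", "G2"], labels, "a", "b", min_pct=0.2)
        assert res == []

    def test_planted_effect_recovered(self):
        matrix, labels, truth = simulate_counts(
            300, 250, seed=5, n_planted=20, planted_log2fc=2.0
        )
        norm = normalize_cells(matrix)
        res = wilcoxon_de(norm, matrix.gene_ids, labels, "Ri_AIE", "AgD")
        flagged = {
            r.gene for r in res if r.significant_up or r.significant_down
        }
        planted = set(truth.de_genes)
        assert len(flagged & planted) / len(planted) >= 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_de(np.ones((1, 3)), ["G"], ["a", "a", "a"], "a", "b")

    def test_direction_convention(self):
        # group1 higher -> positive avg_log2fc and significant_up
        norm = np.zeros((1, 60))
        norm[0, :30] = np.linspace(2, 3, 30)
        labels = ["hi"] * 30 + ["lo"] * 30
        (res,) = wilcoxon_de(norm, ["G1"], labels, "hi", "lo", min_pct=0.0)
        assert res.avg_log2fc > 0.5 and res.significant_up


class TestBH:
    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_against_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40)).tolist()
            np.testing.assert_allclose(
                bh_adjust(p), bh_stepup_oracle(p), rtol=1e-12
            )

    def test_deterministic_monotone_fixed_point(self):
        # re-running BH on already-adjusted values is NOT the identity
        # (the n/k factor applies again); the stable properties are
        # determinism, monotonicity along sorted raw p, and the adjusted
        # vector being a fixed point of the step-up monotonization
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25).tolist()
        adj = np.array(bh_adjust(p))
        assert bh_adjust(p) == pytest.approx(adj)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        monotonized = np.minimum.accumulate(adj[order][::-1])[::-1]
        np.testing.assert_allclose(adj[order], monotonized, rtol=1e-12)

    def test_rejection_set_matches_stepup_rule(self):
        rng = np.random.default_rng(8)
        for alpha in (0.05, 0.1):
            p = np.sort(rng.uniform(size=30) ** 2)
            adj = np.array(bh_adjust(p.tolist()))
            n = len(p)
            ks = np.flatnonzero(p <= alpha * np.arange(1, n + 1) / n)
            stepup = set(range(ks[-1] + 1)) if len(ks) else set()
            assert set(np.flatnonzero(adj <= alpha)) == stepup

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestPseudobulk:
    def matrix(self, arr, barcodes=None):
        arr = np.asarray(arr)
        return CountsMatrix(
            gene_ids=[f"G{i}" for i in range(arr.shape[0])],
            barcodes=barcodes or [f"B{j}" for j in range(arr.shape[1])],
            values=sp.csr_matrix(arr),
        )

    def test_sums_within_donor(self):
        pb = pseudobulk(self.matrix([[3, 7]]), ["D1", "D1"])
        assert pb.counts.tolist() == [[10]]

    def test_one_cell_per_donor_is_identity(self):
        arr = np.array([[1, 2], [3, 4]])
        pb = pseudobulk(self.matrix(arr), ["D1", "D2"])
        np.testing.assert_array_equal(pb.counts, arr)

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(2.0, size=(20, 30))
        labels = rng.choice(["D1", "D2", "D3"], size=30).tolist()
        pb = pseudobulk(self.matrix(arr), labels)
        assert pb.counts.sum() == arr.sum()
        for j, s in enumerate(pb.sample_ids):
            cols = [k for k, l in enumerate(labels) if l == s]
            np.testing.assert_array_equal(
                pb.counts[:, j], arr[:, cols].sum(axis=1)
            )

    def test_unlabeled_cell_rejected(self):
        with pytest.raises(ValidationError):
            pseudobulk(self.matrix([[1, 2]]), ["D1", None])

    def test_fpm_columns_sum_to_million(self):
        rng = np.random.default_rng(9)
        pb = pseudobulk(
            self.matrix(rng.poisson(5.0, size=(15, 12)) + 1),
            (["D1"] * 4 + ["D2"] * 4 + ["D3"] * 4),
        )
        np.testing.assert_allclose(
            pb.per_million.sum(axis=0), [1e6] * 3, atol=1e-6
        )

    def test_fpm_simple_values(self):
        pb = PseudobulkMatrix(
            sample_ids=["S"], gene_ids=["G1", "G2"],
            counts=np.array([[5], [45]]),
        )
        fpm = fpm_normalize(pb)
        assert fpm[0, 0] == pytest.approx(1e5)

    def test_fpm_zero_total_rejected(self):
        pb = PseudobulkMatrix(
            sample_ids=["S"], gene_ids=["G1"], counts=np.array([[0]])
        )
        with pytest.raises(ValidationError):
            fpm_normalize(pb)


class TestExactTests:
    def test_signed_rank_uniform_signs_n6(self):
        assert exact_signed_rank([1, 2, 3, 4, 5, 6], [0] * 6) == pytest.approx(
            0.03125
        )

    def test_signed_rank_symmetric_pair(self):
        assert exact_signed_rank([1, 0], [0, 1]) == 1.0

    def test_signed_rank_two_positive_pairs(self):
        # enumeration over the 4 sign assignments: both tails at the
        # extreme sum give 2 * 1/4
        assert exact_signed_rank([1, 2], [0, 0]) == pytest.approx(0.5)

    def test_signed_rank_drops_zero_differences(self):
        assert exact_signed_rank([1, 2, 5], [1, 0, 0]) == exact_signed_rank(
            [2, 5], [0, 0]
        )

    def test_signed_rank_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            exact_signed_rank([1, 2], [1, 2])

    def test_signed_rank_matches_scipy_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            ours = exact_signed_rank(a, b)
            ref = scipy.stats.wilcoxon(a, b, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_rank_sum_extreme_separation(self):
        assert exact_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_rank_sum_matches_scipy_exact(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert exact_rank_sum(x, y) == pytest.approx(ref, abs=1e-12)


def test_normal_approximation_close_to_exact():
    """Asymptotic rank-sum p with continuity correction stays within 0.02
    of exact enumeration for group sizes 8-25 without ties."""
    rng = np.random.default_rng(21)
    for _ in range(15):
        n1 = int(rng.integers(8, 26))
        n2 = int(rng.integers(8, 26))
        x = rng.normal(size=n1)
        y = rng.normal(0.4, size=n2)
        exact = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact"
        ).pvalue
        approx = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(exact - approx) < 0.02


def test_label_permutation_null_is_uniform():
    """Permuting group labels yields uniform p-values (KS vs uniform)."""
    matrix, labels, _ = simulate_counts(2000, 200, seed=17)
    rng = np.random.default_rng(17)
    perm = rng.permutation(labels)
    norm = normalize_cells(matrix)
    res = wilcoxon_de(norm, matrix.gene_ids, perm, "Ri_AIE", "AgD", min_pct=0.05)
    pvals = np.array([r.p_value for r in res])
    ks = scipy.stats.kstest(pvals, "uniform").statistic
    assert ks < 0.05
    assert sum(r.significant_up or r.significant_down for r in res) == 0


def test_pseudobulk_rank_de_runs_small_cohorts():
    matrix, labels, truth = simulate_counts(
        50, 40, seed=23, n_planted=6, planted_log2fc=3.0
    )
    donor = [
        f"{lab}.d{i % 4}" for i, lab in enumerate(labels)
    ]  # 4 pseudo-donors per group
    pb = pseudobulk(matrix, donor)
    groups = [s.split(".")[0] for s in pb.sample_ids]
    df = pseudobulk_rank_de(pb, groups, "Ri_AIE", "AgD")
    assert set(df.columns) >= {"gene", "p_value", "adj_p_value"}
    assert ((df.p_value >= 0) & (df.p_value <= 1)).all()
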