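"""Partition enumeration, the sum-of-squares ratio statistic, nominal
p-values, and per-interval scanning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from htreeqa import (
    Partition,
    PhenotypeVector,
    ScanConfig,
    build_perfect_phylogeny,
    enumerate_partitions,
    f_statistic,
    nominal_p,
    scan_interval,
)
from htreeqa.association import DEGENERATE_P, _group_sums
from htreeqa import decide_compatibility
from htreeqa.compatibility import CompatibleInterval

from conftest import anova_sums


def star_tree(k, with_center_sample=True):
    """k pendant samples around a center; optionally a sample at the root."""
    n = k + 1 if with_center_sample else k
    binary = np.zeros((n, k), dtype=int)
    for i in range(k):
        # with a center sample, sample 0 keeps the all-zero (root) state
        binary[i + (1 if with_center_sample else 0), i] = 1
    return build_perfect_phylogeny(binary)


def pheno(values):
    values = np.asarray(values, dtype=float)
    return PhenotypeVector(values, tuple(f"s{i}" for i in range(len(values))))


class TestEnumeratePartitions:
    def test_one_cut_gives_two_groups(self, worked_matrix):
        sel = decide_compatibility(worked_matrix, worked_matrix.interval(0, 4))
        from htreeqa import build_tristate_tree

        tree = build_tristate_tree(
            worked_matrix,
            CompatibleInterval(ref=worked_matrix.interval(0, 4), selection=sel),
        )
        for part in enumerate_partitions(tree, max_cut=1):
            assert part.n_groups == 2
            assert len(part.removed_edges) == 1

    def test_x_plus_one_rule(self):
        tree = star_tree(5)
        for part in enumerate_partitions(tree, max_cut=3):
            assert part.n_groups == len(part.removed_edges) + 1

    @pytest.mark.parametrize("k", [3, 4, 6])
    def test_star_tree_count_matches_subset_oracle(self, k):
        """With a sample at every node, removing any edge subset is valid:
        the count is sum_x C(k, x)."""
        tree = star_tree(k)
        got = sum(1 for _ in enumerate_partitions(tree, max_cut=k))
        assert got == sum(math.comb(k, x) for x in range(1, k + 1))

    def test_min_group_filters_empty_center(self):
        """Without a root sample, cutting all k edges strands an empty
        center component, which min_group >= 1 rejects."""
        k = 4
        tree = star_tree(k, with_center_sample=False)
        got = list(enumerate_partitions(tree, max_cut=k))
        # only the all-edge cut is excluded: any smaller cut leaves the
        # center component with at least one pendant sample
        assert len(got) == sum(math.comb(k, x) for x in range(1, k))

    def test_deterministic_order(self):
        tree = star_tree(4)
        seqs = [
            [p.removed_edges for p in enumerate_partitions(tree, max_cut=2)]
            for _ in range(2)
        ]
        assert seqs[0] == seqs[1]
        assert seqs[0][:5] == [(0,), (1,), (2,), (3,), (0, 1)]


class TestFStatistic:
    def test_worked_example_perfect_separation(self):
        # groups {A,B,D} = (10,10,10), {C} = (2), {E} = (2)
        part = Partition(groups=((0, 1, 3), (2,), (4,)), removed_edges=(0, 1))
        values = pheno([10, 10, 2, 10, 2])
        f, degenerate = f_statistic(part, values)
        assert degenerate and math.isinf(f)
        between, within, sst, _ = _group_sums(
            np.array([10.0, 10, 2, 10, 2]), np.array([0, 0, 1, 0, 2]), 3
        )
        assert between == pytest.approx(76.8)
        assert within == pytest.approx(0.0)

    def test_constant_phenotype_is_zero(self):
        part = Partition(groups=((0, 1), (2, 3)), removed_edges=(0,))
        f, degenerate = f_statistic(part, pheno([5, 5, 5, 5]))
        assert f == 0.0 and not degenerate

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            labels = rng.integers(0, 3, size=12)
            while len(np.unique(labels)) < 3:
                labels = rng.integers(0, 3, size=12)
            values = rng.normal(size=12)
            groups = tuple(
                tuple(np.flatnonzero(labels == g)) for g in range(3)
            )
            part = Partition(groups=groups, removed_edges=(0, 1))
            f, degenerate = f_statistic(part, pheno(values))
            b, w = anova_sums(values, labels)
            assert not degenerate
            assert f == pytest.approx(b / w, rel=1e-9)

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=6, max_size=6
        ),
        st.floats(-50, 50, allow_nan=False),
        st.floats(0.1, 20, allow_nan=False),
    )
    def test_shift_invariant_and_anova_identity(self, values, shift, scale):
        """Numerator + denominator = total SS; the ratio is invariant to
        affine changes of the phenotype scale."""
        part = Partition(groups=((0, 1, 2), (3, 4), (5,)), removed_edges=(0, 1))
        values = np.asarray(values)
        b, w, sst, _ = _group_sums(values, np.array([0, 0, 0, 1, 1, 2]), 3)
        assert b + w == pytest.approx(sst, rel=1e-9, abs=1e-9)
        f1, d1 = f_statistic(part, pheno(values))
        f2, d2 = f_statistic(part, pheno(values * scale + shift))
        assert d1 == d2
        if not d1 and np.isfinite(f1):
            assert f2 == pytest.approx(f1, rel=1e-6, abs=1e-9)

    def test_empty_group_rejected(self):
        part = Partition(groups=((0, 1), ()), removed_edges=(0,))
        with pytest.raises(ValueError, match="empty group"):
            f_statistic(part, pheno([1.0, 2.0]))


class TestNominalP:
    def exhaustive_perm_p(self, values, labels):
        """Fraction of all label-preserving value assignments whose ratio
        statistic reaches the observed one (independent oracle)."""
        values = np.asarray(values, dtype=float)
        b, w = anova_sums(values, labels)
        obs = np.inf if w == 0 and b > 0 else (0.0 if b == 0 and w == 0 else b / w)
        count = total = 0
        for perm in itertools.permutations(values):
            pb, pw = anova_sums(np.array(perm), labels)
            stat = np.inf if pw == 0 and pb > 0 else (0.0 if pb == 0 else pb / pw)
            count += stat >= obs
            total += 1
        return count / total

    def test_two_tight_groups(self):
        """Two groups of three with constant within-group values: the
        parametric p hits the degenerate sentinel and the permutation p
        matches the exhaustive count 2/20."""
        values = [1.0, 1.0, 1.0, 9.0, 9.0, 9.0]
        labels = np.array([0, 0, 0, 1, 1, 1])
        part = Partition(groups=((0, 1, 2), (3, 4, 5)), removed_edges=(0,))
        assert nominal_p(part, pheno(values), mode="parametric") == DEGENERATE_P
        assert nominal_p(part, pheno(values), mode="parametric") < 1e-6
        exact = self.exhaustive_perm_p(values, labels)
        assert exact == pytest.approx(2 / 20)
        sampled = nominal_p(
            part, pheno(values), mode="permutation", n_perm=4000, rng_seed=5
        )
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_constant_phenotype_p_one(self):
        part = Partition(groups=((0, 1), (2, 3)), removed_edges=(0,))
        assert nominal_p(part, pheno([3, 3, 3, 3]), mode="parametric") == 1.0
        assert (
            nominal_p(part, pheno([3, 3, 3, 3]), mode="permutation", n_perm=50)
            == 1.0
        )

    def test_parametric_matches_scipy_oneway(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        values = rng.normal(size=9)
        part = Partition(groups=((0, 1, 2), (3, 4, 5), (6, 7, 8)), removed_edges=(0, 1))
        got = nominal_p(part, pheno(values), mode="parametric")
        ref = stats.f_oneway(values[:3], values[3:6], values[6:]).pvalue
        assert got == pytest.approx(ref, rel=1e-9)

    def test_too_few_samples_directs_to_permutation(self):
        part = Partition(groups=((0,), (1,), (2,)), removed_edges=(0, 1))
        with pytest.raises(ValueError, match="permutation"):
            nominal_p(part, pheno([1.0, 2.0, 3.0]), mode="parametric")

    def test_seeded_permutation_reproducible(self):
        part = Partition(groups=((0, 1, 2), (3, 4, 5)), removed_edges=(0,))
        values = pheno([1.0, 2.0, 1.5, 4.0, 3.5, 5.0])
        p1 = nominal_p(part, values, mode="permutation", n_perm=200, rng_seed=9)
        p2 = nominal_p(part, values, mode="permutation", n_perm=200, rng_seed=9)
        assert p1 == p2

    def test_add_one_correction(self):
        part = Partition(groups=((0, 1, 2), (3, 4, 5)), removed_edges=(0,))
        values = pheno([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        plain = nominal_p(part, values, mode="permutation", n_perm=100, rng_seed=2)
        corrected = nominal_p(
            part, values, mode="permutation", n_perm=100, rng_seed=2, add_one=True
        )
        assert corrected > plain
        assert corrected >= 1 / 101


class TestScanInterval:
    def test_worked_example_best_partition(self, worked_matrix, worked_phenotype):
        """The recessive phenotype (2 for C, E; 10 otherwise) is best
        explained by the split along the second marker's edge."""
        ref = worked_matrix.interval(0, 4)
        sel = decide_compatibility(worked_matrix, ref)
        interval = CompatibleInterval(ref=ref, selection=sel)
        res = scan_interval(worked_matrix, interval, worked_phenotype)
        groups = {frozenset(g) for g in res.best_partition.groups}
        assert frozenset({2, 4}) in groups  # {C, E}
        assert frozenset({0, 1, 3}) in groups  # {A, B, D}
        assert res.degenerate
        assert res.nominal_p == DEGENERATE_P
        # the cut edge is labelled by the second marker
        labels = {cid for edge in res.removed_edge_labels for cid, _ in edge}
        assert 1 in labels

    def test_tie_breaks_prefer_fewer_edges(self, worked_matrix, worked_phenotype):
        ref = worked_matrix.interval(0, 4)
        sel = decide_compatibility(worked_matrix, ref)
        interval = CompatibleInterval(ref=ref, selection=sel)
        res = scan_interval(worked_matrix, interval, worked_phenotype)
        # a 1-cut partition achieves the sentinel; no 2-cut should replace it
        assert len(res.best_partition.removed_edges) == 1

    def test_max_cut_one_counts(self, worked_matrix, worked_phenotype):
        ref = worked_matrix.interval(0, 4)
        sel = decide_compatibility(worked_matrix, ref)
        interval = CompatibleInterval(ref=ref, selection=sel)
        cfg = ScanConfig(max_cut=1)
        res = scan_interval(worked_matrix, interval, worked_phenotype, cfg)
        from htreeqa import build_tristate_tree

        tree = build_tristate_tree(worked_matrix, interval)
        assert res.n_partitions == tree.n_edges

    def test_missing_phenotype_dropped_from_scoring(self, worked_matrix):
        values = PhenotypeVector(
            np.array([10.0, 10.0, 2.0, np.nan, 2.0]), worked_matrix.samples
        )
        ref = worked_matrix.interval(0, 4)
        sel = decide_compatibility(worked_matrix, ref)
        interval = CompatibleInterval(ref=ref, selection=sel)
        res = scan_interval(worked_matrix, interval, values)
        assert res.nominal_p <= 1.0  # scored without sample D
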