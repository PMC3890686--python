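import itertools
import math

import numpy as np
import pytest

from barcodegap import (
    PartitionError,
    boxplot_stats,
    gap_summary,
    partition_distances,
    rank_sum_test,
    specimen_gap_table,
)
from tests.conftest import make_dataset, make_dm


def enumeration_rank_sum_p(x, y) -> float:
    """Exhaustive two-sided rank-sum p-value: enumerate every assignment of
    the pooled values into groups of the observed sizes and count rank sums
    at least as extreme (by distance from the mean) as the observed one."""
    pooled = np.concatenate([x, y])
    order = np.sort(pooled)
    # midranks (handles ties, though callers pass tie-free data)
    ranks = np.array([np.mean(np.where(order == v)[0] + 1.0) for v in pooled])
    nx = len(x)
    obs = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestPartition:
    def test_two_by_two_combinatorics(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        ds = make_dataset(labels)
        d = np.array(
            [
                [0, 0.01, 0.1, 0.11],
                [0.01, 0, 0.12, 0.13],
                [0.1, 0.12, 0, 0.02],
                [0.11, 0.13, 0.02, 0],
            ]
        )
        part = partition_distances(make_dm(tuple(labels), d), ds)
        assert len(part.intra) == 2
        assert len(part.inter) == 4

    def test_study_scale_pair_counts(self, clean_sim, clean_dm):
        """Sum of within-species pair counts for sizes {9,12,4,11,20} plus the
        between-species remainder must cover all 56*55/2 pairs."""
        sizes = (9, 12, 4, 11, 20)
        expected_intra = sum(k * (k - 1) // 2 for k in sizes)
        part = partition_distances(clean_dm, clean_sim.dataset)
        assert len(part.intra) == expected_intra == 353
        assert len(part.inter) == 56 * 55 // 2 - expected_intra == 1187

    def test_single_species_is_an_error(self):
        labels = {"a": "A", "b": "A", "c": "A"}
        dm = make_dm(tuple(labels), np.full((3, 3), 0.1) - 0.1 * np.eye(3))
        with pytest.raises(PartitionError):
            partition_distances(dm, make_dataset(labels))


class TestRankSum:
    def test_exact_small_case(self):
        """intra {1,2} vs inter {3,4}: 6 equally likely rank assignments, the
        observed split is one of the two most extreme -> two-sided p = 1/3."""
        p_two, p_greater, method = rank_sum_test(
            np.array([1.0, 2.0]), np.array([3.0, 4.0])
        )
        assert method == "exact"
        assert p_two == pytest.approx(1 / 3)
        assert p_greater == pytest.approx(1 / 6)

    def test_matches_enumeration_on_small_no_tie_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            vals = rng.permutation(rng.random(nx + ny))
            x, y = vals[:nx], vals[nx:]
            p_two, _, method = rank_sum_test(x, y)
            assert method == "exact"
            assert p_two == pytest.approx(enumeration_rank_sum_p(x, y), abs=1e-9)

    def test_large_or_tied_samples_use_asymptotic(self):
        x = np.zeros(30)
        y = np.ones(30)
        _, _, method = rank_sum_test(x, y)
        assert method == "asymptotic"


class TestGapSummary:
    def test_extreme_separation_flags_gap(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        d = np.array(
            [
                [0, 0.0, 0.1, 0.1],
                [0.0, 0, 0.1, 0.1],
                [0.1, 0.1, 0, 0.0],
                [0.1, 0.1, 0.0, 0],
            ]
        )
        s = gap_summary(partition_distances(make_dm(tuple(labels), d), make_dataset(labels)))
        assert s.gap_by_extremes and s.gap_by_median
        assert s.intra_max < s.inter_min

    def test_study_conditions_show_significant_gap(self, clean_sim, clean_dm):
        s = gap_summary(partition_distances(clean_dm, clean_sim.dataset))
        assert s.inter_median > s.intra_median
        assert s.wilcoxon_p < 0.001
        assert s.wilcoxon_p_greater < 0.001
        assert s.intra_min <= s.intra_median <= s.intra_max
        assert s.inter_min <= s.inter_median <= s.inter_max


class TestSpecimenGapTable:
    def test_gap_and_reversed_cases(self):
        labels = {"q": "A", "a2": "A", "b1": "B"}
        d = np.array(
            [
                [0, 0.02, 0.12],
                [0.02, 0, 0.1],
                [0.12, 0.1, 0],
            ]
        )
        recs = {
            r.specimen_id: r
            for r in specimen_gap_table(make_dm(tuple(labels), d), make_dataset(labels))
        }
        assert recs["q"].max_intra == pytest.approx(0.02)
        assert recs["q"].min_inter == pytest.approx(0.12)
        assert recs["q"].has_gap is True
        # nearest non-conspecific closer than the conspecific -> no gap
        labels2 = {"q": "A", "a2": "A", "b1": "B"}
        d2 = np.array(
            [
                [0, 0.05, 0.003],
                [0.05, 0, 0.06],
                [0.003, 0.06, 0],
            ]
        )
        recs2 = {
            r.specimen_id: r
            for r in specimen_gap_table(make_dm(tuple(labels2), d2), make_dataset(labels2))
        }
        assert recs2["q"].has_gap is False

    def test_singleton_species_reported_na(self):
        labels = {"a1": "A", "a2": "A", "lone": "B"}
        d = np.array(
            [
                [0, 0.01, 0.1],
                [0.01, 0, 0.1],
                [0.1, 0.1, 0],
            ]
        )
        recs = {
            r.specimen_id: r
            for r in specimen_gap_table(make_dm(tuple(labels), d), make_dataset(labels))
        }
        assert recs["lone"].max_intra is None
        assert recs["lone"].has_gap is None
        assert recs["lone"].min_inter == pytest.approx(0.1)

    def test_all_specimens_have_gap_under_strong_separation(self, clean_sim, clean_dm):
        """With interspecific divergence ~35x intraspecific, every specimen's
        nearest non-conspecific is beyond its furthest conspecific."""
        recs = specimen_gap_table(clean_dm, clean_sim.dataset)
        assert all(r.has_gap for r in recs if r.has_gap is not None)
        assert all(r.has_gap is not None for r in recs)  # no singleton species


def test_boxplot_stats_tukey_convention():
    vals = np.array([0.0, 0.01, 0.012, 0.013, 0.014, 0.015, 0.5])
    s = boxplot_stats(vals)
    assert s["q1"] <= s["median"] <= s["q3"]
    # q1=0.011, q3=0.0145 -> fences at q1-1.5*iqr=0.00575 and q3+1.5*iqr=0.01975
    assert s["outliers"] == [0.0, 0.5]
    assert s["whisker_low"] == pytest.approx(0.01)
    assert s["whisker_high"] == pytest.approx(0.015)
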