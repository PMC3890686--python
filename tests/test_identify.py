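import numpy as np
import pytest

from barcodegap import (
    PartitionError,
    best_close_match,
    evaluate_all,
    near_neighbour,
    percentage,
    thresh_id,
)
from tests.conftest import make_dm

# One query "q" (species A) against four candidates with adjustable distances.
IDS = ("q", "a1", "a2", "b1", "b2")
LABELS = {"q": "A", "a1": "A", "a2": "A", "b1": "B", "b2": "B"}


def dm_with_query_row(row: dict[str, float]):
    """Distance matrix where only the query row matters for the tests."""
    n = len(IDS)
    d = np.full((n, n), 0.2)
    np.fill_diagonal(d, 0.0)
    for sid, val in row.items():
        j = IDS.index(sid)
        d[0, j] = d[j, 0] = val
    return make_dm(IDS, d)


class TestBestCloseMatch:
    def test_nearest_conspecific_within_threshold_correct(self):
        dm = dm_with_query_row({"a1": 0.01, "a2": 0.03, "b1": 0.1, "b2": 0.12})
        out = best_close_match("q", dm, LABELS, threshold=0.047)
        assert out.outcome == "correct"
        assert out.matched_ids == ("a1",)

    def test_nothing_within_threshold_no_id(self):
        dm = dm_with_query_row({"a1": 0.06, "a2": 0.07, "b1": 0.1, "b2": 0.12})
        out = best_close_match("q", dm, LABELS, threshold=0.047)
        assert out.outcome == "no_id"
        assert out.matched_ids == ()

    def test_mixed_tie_is_ambiguous(self):
        dm = dm_with_query_row({"a1": 0.01, "b1": 0.01, "a2": 0.05, "b2": 0.1})
        out = best_close_match("q", dm, LABELS, threshold=0.047)
        assert out.outcome == "ambiguous"
        assert set(out.matched_ids) == {"a1", "b1"}

    def test_heterospecific_nearest_incorrect(self):
        dm = dm_with_query_row({"b1": 0.01, "a1": 0.03, "a2": 0.05, "b2": 0.1})
        out = best_close_match("q", dm, LABELS, threshold=0.047)
        assert out.outcome == "incorrect"

    def test_near_tie_within_relative_tolerance_counts(self):
        d = 0.01
        dm = dm_with_query_row({"a1": d, "b1": d * (1 + 1e-13), "a2": 0.05, "b2": 0.1})
        out = best_close_match("q", dm, LABELS, threshold=0.047)
        assert out.outcome == "ambiguous"


class TestNearNeighbour:
    def test_nearest_conspecific_true(self):
        dm = dm_with_query_row({"a1": 0.01, "a2": 0.03, "b1": 0.1, "b2": 0.12})
        assert near_neighbour("q", dm, LABELS).outcome == "true"

    def test_nearest_heterospecific_false(self):
        dm = dm_with_query_row({"b1": 0.005, "a1": 0.01, "a2": 0.03, "b2": 0.1})
        assert near_neighbour("q", dm, LABELS).outcome == "false"

    def test_tie_with_any_conspecific_true(self):
        """Tie rule: conspecific among the tied nearest suffices, confirmed
        against exhaustive enumeration of nearest sets."""
        dm = dm_with_query_row({"a1": 0.01, "b1": 0.01, "a2": 0.05, "b2": 0.1})
        out = near_neighbour("q", dm, LABELS)
        # exhaustive oracle: the nearest set by scanning all candidates
        row = {sid: dm.value("q", sid) for sid in IDS if sid != "q"}
        m = min(row.values())
        nearest = {sid for sid, v in row.items() if v <= m * (1 + 1e-12)}
        assert nearest == {"a1", "b1"}
        assert out.outcome == "true"


class TestThreshID:
    def test_only_conspecifics_within_threshold_correct(self):
        dm = dm_with_query_row({"a1": 0.005, "a2": 0.009, "b1": 0.1, "b2": 0.12})
        assert thresh_id("q", dm, LABELS).outcome == "correct"

    def test_mixed_candidates_ambiguous(self):
        dm = dm_with_query_row({"a1": 0.005, "b1": 0.008, "a2": 0.05, "b2": 0.1})
        out = thresh_id("q", dm, LABELS)
        assert out.outcome == "ambiguous"
        assert set(out.matched_ids) == {"a1", "b1"}

    def test_nothing_within_threshold_no_id(self):
        dm = dm_with_query_row({"a1": 0.02, "a2": 0.03, "b1": 0.1, "b2": 0.12})
        assert thresh_id("q", dm, LABELS).outcome == "no_id"

    def test_boundary_is_inclusive(self):
        dm = dm_with_query_row({"a1": 0.01, "a2": 0.03, "b1": 0.1, "b2": 0.12})
        assert thresh_id("q", dm, LABELS, threshold=0.01).outcome == "correct"

    def test_extreme_thresholds(self, study_dm, study_sim):
        """threshold -> inf never yields no_id; threshold -> 0+ on strictly
        positive distances always yields no_id."""
        labels = study_sim.observed_labels
        qi = study_dm.ids[0]
        assert thresh_id(qi, study_dm, labels, threshold=np.inf).outcome != "no_id"
        positive = [
            sid
            for i, sid in enumerate(study_dm.ids)
            if np.all(np.delete(study_dm.d[i], i) > 0)
        ]
        if positive:
            out = thresh_id(positive[0], study_dm, labels, threshold=1e-15)
            assert out.outcome == "no_id"


class TestEvaluateAll:
    def test_perfect_separation_scores_everything_correct(self, clean_sim, clean_dm):
        report = evaluate_all(clean_dm, clean_sim.true_species, bcm_threshold=0.047)
        df = report.summary().set_index(["criterion", "outcome"])
        n = clean_dm.n
        assert df.loc[("near_neighbour", "true"), "n"] == n
        assert df.loc[("best_close_match", "correct"), "n"] == n
        assert df.loc[("best_close_match", "correct"), "percent"] == 100.0

    def test_counts_sum_to_n_and_percentages_to_100(self, study_dm, study_sim):
        report = evaluate_all(study_dm, study_sim.observed_labels, bcm_threshold=0.047)
        df = report.summary()
        for criterion, sub in df.groupby("criterion"):
            assert sub["n"].sum() == study_dm.n
            assert sub["percent"].sum() == pytest.approx(100.0, abs=0.02)

    def test_agreement_between_bcm_and_nn_on_unique_nearest(self, study_dm, study_sim):
        """Whenever the nearest candidate is unique and within threshold the
        two criteria agree (correct <=> true)."""
        labels = study_sim.observed_labels
        rep = evaluate_all(study_dm, labels, bcm_threshold=0.5)
        by = {}
        for o in rep.outcomes:
            by.setdefault(o.specimen_id, {})[o.criterion] = o
        for sid, outs in by.items():
            bcm, nn = outs["best_close_match"], outs["near_neighbour"]
            if len(nn.matched_ids) == 1:
                assert (bcm.outcome == "correct") == (nn.outcome == "true")

    def test_raising_bcm_threshold_never_creates_no_id(self, study_dm, study_sim):
        labels = study_sim.observed_labels
        low = evaluate_all(study_dm, labels, bcm_threshold=0.01)
        high = evaluate_all(study_dm, labels, bcm_threshold=0.2)
        low_noid = {
            o.specimen_id
            for o in low.outcomes
            if o.criterion == "best_close_match" and o.outcome == "no_id"
        }
        high_by_id = {
            o.specimen_id: o.outcome
            for o in high.outcomes
            if o.criterion == "best_close_match"
        }
        for sid, outcome in high_by_id.items():
            if sid not in low_noid:
                assert outcome != "no_id"

    def test_single_species_rejected(self):
        dm = make_dm(("a", "b"), np.array([[0, 0.01], [0.01, 0]]))
        with pytest.raises(PartitionError):
            evaluate_all(dm, {"a": "X", "b": "X"}, bcm_threshold=0.05)


@pytest.mark.parametrize(
    "count,total,expected",
    [(3, 56, 5.36), (27, 56, 48.21), (49, 56, 87.5), (7, 56, 12.5), (1, 56, 1.79), (4, 56, 7.14)],
)
def test_percentage_printed_convention(count, total, expected):
    assert percentage(count, total) == expected
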