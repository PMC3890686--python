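"""Leave-one-out specimen identification under three criteria.

Each specimen in turn is treated as an unknown query against the database
of all remaining specimens:

* **best close match** — look at the closest candidate(s); no candidate
  within the threshold gives ``no_id``; otherwise the tied-nearest set
  decides: all conspecific → ``correct``, all heterospecific →
  ``incorrect``, mixed → ``ambiguous``.
* **near neighbour** — ``true`` iff at least one tied-nearest candidate is
  conspecific, with no distance threshold.
* **threshold identification** (the BOLD "Identify Specimen" rule,
  emulated locally) — consider every candidate within a fixed threshold
  (1% by default): empty set → ``no_id``, all conspecific → ``correct``,
  mixed → ``ambiguous``, only heterospecific → ``incorrect``.

Ties: candidates within a relative ``1e-12`` of the minimum distance count
as tied-nearest (exact float equality is too brittle for recomputed
matrices).  Threshold comparisons are inclusive (``d <= threshold``).
Percentages are rounded half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import AlignmentError, PartitionError

BOLD_DEFAULT_THRESHOLD = 0.01
TIE_RELATIVE_TOLERANCE = 1e-12

CRITERIA = ("near_neighbour", "best_close_match", "thresh_id")
#: Outcome vocabulary per criterion, in report order.
OUTCOMES = {
    "near_neighbour": ("true", "false"),
    "best_close_match": ("correct", "incorrect", "ambiguous", "no_id"),
    "thresh_id": ("correct", "incorrect", "ambiguous", "no_id"),
}


@dataclass(frozen=True)
class IdentificationOutcome:
    specimen_id: str
    criterion: str
    outcome: str
    matched_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES[self.criterion]:
            raise ValueError(
                f"outcome {self.outcome!r} invalid for criterion {self.criterion!r}"
            )


@dataclass(frozen=True)
class IdentificationReport:
    """All per-specimen outcomes plus a criterion × outcome summary table."""

    outcomes: tuple[IdentificationOutcome, ...]
    thresholds: dict[str, float | None] = field(default_factory=dict)

    @property
    def n_specimens(self) -> int:
        return len({o.specimen_id for o in self.outcomes})

    def summary(self) -> pd.DataFrame:
        """Counts and half-up two-decimal percentages per criterion/outcome."""
        n = self.n_specimens
        rows = []
        for criterion in CRITERIA:
            scored = [o for o in self.outcomes if o.criterion == criterion]
            for outcome in OUTCOMES[criterion]:
                count = sum(1 for o in scored if o.outcome == outcome)
                rows.append(
                    {
                        "criterion": criterion,
                        "outcome": outcome,
                        "n": count,
                        "percent": percentage(count, n),
                    }
                )
        return pd.DataFrame(rows)


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-up to 2 decimals (report convention)."""
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _candidates(query: str, dm: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    """Non-self candidate IDs and their distances to the query (NaN dropped)."""
    qi = dm.index(query)
    ids, dists = [], []
    for j, other in enumerate(dm.ids):
        if j == qi or np.isnan(dm.d[qi, j]):
            continue
        ids.append(other)
        dists.append(float(dm.d[qi, j]))
    if not ids:
        raise AlignmentError(f"query {query!r} has no usable candidates")
    return ids, np.array(dists)


def _nearest_set(ids: list[str], dists: np.ndarray) -> tuple[list[str], float]:
    m = float(dists.min())
    tol = m * TIE_RELATIVE_TOLERANCE
    tied = [sid for sid, d in zip(ids, dists) if d <= m + tol]
    return tied, m


def best_close_match(
    query: str, dm: DistanceMatrix, labels: dict[str, str], threshold: float
) -> IdentificationOutcome:
    """Best-close-match outcome for one query (leave-one-out)."""
    ids, dists = _candidates(query, dm)
    tied, m = _nearest_set(ids, dists)
    if m > threshold:
        return IdentificationOutcome(query, "best_close_match", "no_id")
    species = {labels[t] for t in tied}
    if species == {labels[query]}:
        outcome = "correct"
    elif labels[query] in species:
        outcome = "ambiguous"
    else:
        outcome = "incorrect"
    return IdentificationOutcome(query, "best_close_match", outcome, tuple(tied))


def near_neighbour(
    query: str, dm: DistanceMatrix, labels: dict[str, str]
) -> IdentificationOutcome:
    """Near-neighbour outcome: true iff any tied-nearest candidate is
    conspecific (tie rule; the unique-nearest case is unambiguous)."""
    ids, dists = _candidates(query, dm)
    tied, _ = _nearest_set(ids, dists)
    ok = any(labels[t] == labels[query] for t in tied)
    return IdentificationOutcome(
        query, "near_neighbour", "true" if ok else "false", tuple(tied)
    )


def thresh_id(
    query: str,
    dm: DistanceMatrix,
    labels: dict[str, str],
    threshold: float = BOLD_DEFAULT_THRESHOLD,
) -> IdentificationOutcome:
    """Fixed-threshold outcome over all candidates with d <= threshold."""
    ids, dists = _candidates(query, dm)
    within = [sid for sid, d in zip(ids, dists) if d <= threshold]
    if not within:
        return IdentificationOutcome(query, "thresh_id", "no_id")
    species = {labels[s] for s in within}
    if species == {labels[query]}:
        outcome = "correct"
    elif labels[query] in species:
        outcome = "ambiguous"
    else:
        outcome = "incorrect"
    return IdentificationOutcome(query, "thresh_id", outcome, tuple(within))


def evaluate_all(
    dm: DistanceMatrix,
    labels: dict[str, str],
    bcm_threshold: float,
    tid_threshold: float = BOLD_DEFAULT_THRESHOLD,
) -> IdentificationReport:
    """Score every specimen under all three criteria.

    ``labels`` maps specimen ID to species label; ``bcm_threshold`` is
    typically the optimised density-dip threshold.
    """
    if dm.n < 2:
        raise AlignmentError("identification needs at least 2 specimens")
    if len({labels[i] for i in dm.ids}) < 2:
        raise PartitionError("identification needs at least 2 species")
    outcomes: list[IdentificationOutcome] = []
    for sid in dm.ids:
        outcomes.append(near_neighbour(sid, dm, labels))
        outcomes.append(best_close_match(sid, dm, labels, bcm_threshold))
        outcomes.append(thresh_id(sid, dm, labels, tid_threshold))
    return IdentificationReport(
        outcomes=tuple(outcomes),
        thresholds={
            "near_neighbour": None,
            "best_close_match": bcm_threshold,
            "thresh_id": tid_threshold,
        },
    )
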