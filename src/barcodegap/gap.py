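"""Barcode-gap assessment: intra- vs interspecific distance partitions.

Two complementary views of the gap:

* population level — compare the distance distributions (medians, ranges)
  of conspecific and heterospecific pairs, with a Wilcoxon rank-sum test;
* specimen level — for each specimen compare its furthest conspecific
  against its nearest non-conspecific; a specimen "has a gap" when the
  nearest non-conspecific is further away than every conspecific.

Pairwise distances are statistically non-independent, so the rank-sum
p-value is an as-practised summary, not a calibrated test; reports carry
that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distances import DistanceMatrix
from .errors import PartitionError
from .io import BarcodeDataset

#: Caveat attached to every gap report.
NONINDEPENDENCE_CAVEAT = (
    "Pairwise distances are non-independent; the rank-sum p-value describes "
    "the observed separation and is not a calibrated hypothesis test."
)

Pair = tuple[str, str]


@dataclass(frozen=True)
class DistancePartition:
    """Off-diagonal pairs split into conspecific (intra) and heterospecific
    (inter) sets; together they cover every unordered pair exactly once."""

    intra: tuple[tuple[Pair, float], ...]
    inter: tuple[tuple[Pair, float], ...]

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([d for _, d in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([d for _, d in self.inter], dtype=float)


@dataclass(frozen=True)
class GapSummary:
    """Distribution summary of both partitions plus the rank-sum test."""

    intra_median: float
    intra_min: float
    intra_max: float
    inter_median: float
    inter_min: float
    inter_max: float
    wilcoxon_p: float
    wilcoxon_p_greater: float
    wilcoxon_method: str
    gap_by_median: bool
    gap_by_extremes: bool
    caveat: str = NONINDEPENDENCE_CAVEAT


@dataclass(frozen=True)
class SpecimenGapRecord:
    """Per-specimen barcode-gap record.

    ``max_intra`` (and hence ``has_gap``) is None for members of singleton
    species, which have no conspecific comparison.
    """

    specimen_id: str
    max_intra: float | None
    min_inter: float
    has_gap: bool | None


def partition_distances(
    dm: DistanceMatrix, dataset: BarcodeDataset
) -> DistancePartition:
    """Split all off-diagonal pairs by shared vs differing species label.

    NaN distances (saturated pairs excluded under the "missing" policy) are
    dropped from both sets.  Raises :class:`PartitionError` when only one
    species is present (empty interspecific set).
    """
    labels = dataset.labels
    intra: list[tuple[Pair, float]] = []
    inter: list[tuple[Pair, float]] = []
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            val = float(dm.d[i, j])
            if np.isnan(val):
                continue
            pair = (dm.ids[i], dm.ids[j])
            if labels[pair[0]] == labels[pair[1]]:
                intra.append((pair, val))
            else:
                inter.append((pair, val))
    if not inter:
        raise PartitionError(
            "only one species present: interspecific partition is empty"
        )
    return DistancePartition(intra=tuple(intra), inter=tuple(inter))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Wilcoxon rank-sum p-values for samples ``x`` and ``y``.

    Returns ``(two_sided, one_sided_y_greater, method)``.  Exact null
    distribution when both samples have at most 25 values and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 25 and len(y) <= 25 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    two = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    greater = stats.mannwhitneyu(y, x, alternative="greater", method=method).pvalue
    return float(two), float(greater), method


def gap_summary(partition: DistancePartition) -> GapSummary:
    """Medians, ranges and rank-sum test for a distance partition.

    Even-count medians use the midpoint of the two central values (numpy's
    convention).  ``gap_by_extremes`` is the strict global criterion
    ``min(inter) > max(intra)``.
    """
    intra = partition.intra_values
    inter = partition.inter_values
    if intra.size == 0 or inter.size == 0:
        raise PartitionError("both partitions must be non-empty for a gap summary")
    p_two, p_greater, method = rank_sum_test(intra, inter)
    return GapSummary(
        intra_median=float(np.median(intra)),
        intra_min=float(intra.min()),
        intra_max=float(intra.max()),
        inter_median=float(np.median(inter)),
        inter_min=float(inter.min()),
        inter_max=float(inter.max()),
        wilcoxon_p=p_two,
        wilcoxon_p_greater=p_greater,
        wilcoxon_method=method,
        gap_by_median=bool(np.median(inter) > np.median(intra)),
        gap_by_extremes=bool(inter.min() > intra.max()),
    )


def specimen_gap_table(
    dm: DistanceMatrix, dataset: BarcodeDataset
) -> list[SpecimenGapRecord]:
    """Per-specimen furthest-conspecific vs nearest-non-conspecific table.

    Requires at least two species.  Records for singleton-species specimens
    carry ``max_intra = None`` and ``has_gap = None``.
    """
    labels = dataset.labels
    if len(set(labels[i] for i in dm.ids)) < 2:
        raise PartitionError("specimen gap table requires at least 2 species")
    out: list[SpecimenGapRecord] = []
    for i, sid in enumerate(dm.ids):
        row = dm.d[i]
        same = np.array([labels[o] == labels[sid] for o in dm.ids])
        same[i] = False
        other = ~same
        other[i] = False
        intra_vals = row[same]
        inter_vals = row[other]
        intra_vals = intra_vals[~np.isnan(intra_vals)]
        inter_vals = inter_vals[~np.isnan(inter_vals)]
        max_intra = float(intra_vals.max()) if intra_vals.size else None
        min_inter = float(inter_vals.min())
        has_gap = None if max_intra is None else bool(min_inter > max_intra)
        out.append(
            SpecimenGapRecord(
                specimen_id=sid,
                max_intra=max_intra,
                min_inter=min_inter,
                has_gap=has_gap,
            )
        )
    return out


def boxplot_stats(values: np.ndarray) -> dict[str, object]:
    """Quartiles, whiskers and outliers in the Tukey convention.

    Whiskers extend to the most extreme data point within 1.5 interquartile
    ranges of the box; points beyond are outliers.
    """
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
    }
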