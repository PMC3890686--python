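"""Threshold-linked MOTU delimitation and morphospecies congruence.

A molecular operational taxonomic unit (MOTU) is a connected component of
the graph with an edge between two specimens whenever their distance is at
or below the delimitation threshold.  This is single-linkage "chaining":
two specimens further apart than the threshold still share a MOTU when a
chain of intermediates links them.

MOTU labels are content-derived — components ordered by descending size,
then lexicographically smallest member — so the partition and its labels
are invariant under specimen reordering.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix
from .errors import AlignmentError, PartitionError
from .io import BarcodeDataset


@dataclass(frozen=True)
class MOTUPartition:
    """Disjoint specimen clusters at a fixed threshold.

    ``motus`` maps a stable label ("MOTU_1", ...) to a frozenset of
    specimen IDs.
    """

    threshold: float
    motus: dict[str, frozenset[str]]

    @property
    def n_motus(self) -> int:
        return len(self.motus)

    def motu_of(self, specimen_id: str) -> str:
        for label, members in self.motus.items():
            if specimen_id in members:
                return label
        raise KeyError(specimen_id)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.motus.values())


@dataclass(frozen=True)
class Mismatch:
    specimen_id: str
    species_label: str
    motu_id: str
    majority_species: str
    majority_tied: bool


@dataclass(frozen=True)
class CongruenceReport:
    """MOTU-vs-morphospecies congruence tables.

    ``motu_composition`` maps MOTU label -> {species label: count};
    ``species_spread`` maps species label -> set of MOTU labels; a specimen
    is a mismatch iff its label differs from its MOTU's majority species.
    """

    motu_composition: dict[str, dict[str, int]]
    species_spread: dict[str, frozenset[str]]
    mismatches: tuple[Mismatch, ...]

    @property
    def mismatch_ids(self) -> frozenset[str]:
        return frozenset(m.specimen_id for m in self.mismatches)


def _stable_labels(components: list[set[str]]) -> dict[str, frozenset[str]]:
    ordered = sorted(components, key=lambda c: (-len(c), min(c)))
    return {f"MOTU_{k + 1}": frozenset(c) for k, c in enumerate(ordered)}


def delimit_motus(dm: DistanceMatrix, threshold: float) -> MOTUPartition:
    """Single-linkage MOTUs: connected components of the d <= threshold graph.

    The edge rule is inclusive; NaN (missing) distances never create an
    edge.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    with np.errstate(invalid="ignore"):
        adj = dm.d <= threshold
    adj &= ~np.isnan(dm.d)
    np.fill_diagonal(adj, True)
    n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
    comps: list[set[str]] = [set() for _ in range(n_comp)]
    for sid, c in zip(dm.ids, assignment):
        comps[c].add(sid)
    return MOTUPartition(threshold=float(threshold), motus=_stable_labels(comps))


def congruence_report(
    partition: MOTUPartition, dataset: BarcodeDataset
) -> CongruenceReport:
    """Compare a MOTU partition against morphospecies labels.

    Majority ties within a MOTU are broken lexicographically and flagged on
    every mismatch record from that MOTU.
    """
    if not partition.motus:
        raise PartitionError("empty MOTU partition")
    labels = dataset.labels
    composition: dict[str, dict[str, int]] = {}
    spread: dict[str, set[str]] = collections.defaultdict(set)
    mismatches: list[Mismatch] = []
    for motu_id, members in partition.motus.items():
        counts = collections.Counter(labels[m] for m in members)
        composition[motu_id] = dict(sorted(counts.items()))
        top = max(counts.values())
        winners = sorted(sp for sp, c in counts.items() if c == top)
        majority, tied = winners[0], len(winners) > 1
        for m in sorted(members):
            spread[labels[m]].add(motu_id)
            if labels[m] != majority:
                mismatches.append(
                    Mismatch(
                        specimen_id=m,
                        species_label=labels[m],
                        motu_id=motu_id,
                        majority_species=majority,
                        majority_tied=tied,
                    )
                )
    return CongruenceReport(
        motu_composition=composition,
        species_spread={sp: frozenset(ms) for sp, ms in spread.items()},
        mismatches=tuple(mismatches),
    )


def motu_count_curve(
    dm: DistanceMatrix, thresholds: list[float]
) -> list[tuple[float, int]]:
    """Number of MOTUs at each threshold (non-increasing in the threshold)."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [(float(t), delimit_motus(dm, t).n_motus) for t in thresholds]


def _single_linkage(dm: DistanceMatrix) -> np.ndarray:
    if dm.n < 2:
        raise AlignmentError("dendrogram needs at least 2 specimens")
    if np.isnan(dm.d).any():
        raise ValueError("dendrogram undefined with missing distances")
    return linkage(squareform(dm.d, checks=False), method="single")


def linkage_to_newick(dm: DistanceMatrix) -> str:
    """Single-linkage dendrogram as an ultrametric newick string.

    Node heights are half the merge distance, so the cophenetic distance
    between two leaves equals the single-linkage merge distance between
    their clusters, and cutting the tree where cophenetic distance exceeds
    the threshold reproduces :func:`delimit_motus` exactly (see
    :func:`newick_partition`).
    """
    Z = _single_linkage(dm)
    n = dm.n
    height = {i: 0.0 for i in range(n)}
    node = {i: dm.ids[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        idx = n + k
        node[idx] = (
            f"({node[a]}:{h - height[a]:.10g},{node[b]}:{h - height[b]:.10g})"
        )
        height[idx] = h
    return node[n + len(Z) - 1] + ";"


def newick_partition(newick: str, threshold: float) -> set[frozenset[str]]:
    """Cut an ultrametric dendrogram at a distance threshold.

    Clusters are the maximal clades whose root sits at height (distance to
    its leaves) at most ``threshold / 2``, i.e. whose members are all
    within cophenetic distance ``threshold`` of one another.
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    half = threshold / 2.0 + 1e-12
    clusters: list[frozenset[str]] = []

    def walk(node, cut_done: bool) -> None:
        h = max(
            (leaf_depth[leaf] - depth[node] for leaf in leaves[node]), default=0.0
        )
        if not cut_done and h <= half:
            clusters.append(frozenset(leaves[node]))
            cut_done = True
        for child in node.child_nodes():
            walk(child, cut_done)

    depth: dict = {}
    leaves: dict = {}
    leaf_depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent else 0.0) + edge
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            leaves[node] = {name}
            leaf_depth[name] = depth[node]
        else:
            leaves[node] = set().union(*(leaves[c] for c in node.child_nodes()))
    walk(tree.seed_node, False)
    return set(clusters)
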