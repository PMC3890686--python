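"""Kimura 2-parameter pairwise distances with pairwise deletion.

For each sequence pair, only columns where both members carry an
unambiguous base (A, C, G or T) are compared ("pairwise deletion"); gaps,
N and IUPAC ambiguity codes are treated as missing, never partially
matched.  From the comparable columns the proportions of transitions
(A<->G, C<->T) ``P`` and transversions ``Q`` give the distance

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

in expected substitutions per site.  The correction diverges when the
logarithm arguments reach zero ("saturation"): the default policy is to
raise, naming the pair; an opt-in mode records the pair as missing (NaN)
so downstream pooling can exclude it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, IncomparablePairError, SaturationError
from .io import BarcodeDataset

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SitePairCounts:
    """Comparable-site and difference counts for one sequence pair."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        """Proportion of comparable sites showing a transition."""
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        """Proportion of comparable sites showing a transversion."""
        return self.n_transversions / self.n_sites


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with comparable-site counts.

    ``d`` is a square float array (NaN marks pairs excluded as saturated
    under the "missing" policy); ``n_sites`` the matching comparable-site
    counts.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match number of IDs")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def condensed(self, *, drop_missing: bool = True) -> np.ndarray:
        """Lower-triangle distances as a flat array (NaN dropped by default)."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu]
        if drop_missing:
            vals = vals[~np.isnan(vals)]
        return vals


def _encode(seq: str) -> np.ndarray:
    """Map a sequence onto codes 0..3 for A/C/G/T and 255 for anything else."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for ch, code in _CODE.items():
        table[ord(ch)] = code
    return table[arr]


def count_site_pairs(seq_a: str, seq_b: str) -> SitePairCounts:
    """Count comparable sites, transitions and transversions for one pair.

    A column is comparable iff both characters are unambiguous bases;
    transitions are A<->G and C<->T, any other differing comparable pair is
    a transversion.  Raises :class:`IncomparablePairError` when no column
    is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    comparable = (a < 4) & (b < 4)
    n_sites = int(comparable.sum())
    if n_sites == 0:
        raise IncomparablePairError("no comparable (both-unambiguous) columns")
    diff = comparable & (a != b)
    # A=0/G=2 share parity, as do C=1/T=3: differing same-parity codes are
    # transitions, differing mixed-parity codes transversions.
    transitions = diff & ((a & 1) == (b & 1))
    n_ts = int(transitions.sum())
    n_tv = int(diff.sum()) - n_ts
    return SitePairCounts(n_sites=n_sites, n_transitions=n_ts, n_transversions=n_tv)


def k2p_distance(counts: SitePairCounts) -> float:
    """K2P distance (substitutions/site) from site-pair counts.

    Raises :class:`SaturationError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0``.
    """
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} "
            "(substitution saturation)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(
    dataset: BarcodeDataset,
    *,
    on_saturation: str = "raise",
    exclude_outgroups: bool = True,
) -> DistanceMatrix:
    """All-pairs K2P distances for a dataset, with pairwise deletion.

    Parameters
    ----------
    dataset:
        Joined alignment + metadata.
    on_saturation:
        ``"raise"`` (default) aborts on the first saturated or incomparable
        pair, naming it; ``"missing"`` records such pairs as NaN with a
        logged warning and leaves their exclusion to downstream pooling.
    exclude_outgroups:
        Drop specimens flagged ``outgroup`` before computing (default).
    """
    if on_saturation not in {"raise", "missing"}:
        raise ValueError(f"unknown saturation policy: {on_saturation!r}")
    if exclude_outgroups:
        dataset = dataset.without_outgroups()
    ids = dataset.ids
    n = len(ids)
    if n < 2:
        raise AlignmentError("need at least 2 specimens for a distance matrix")
    codes = np.vstack([_encode(seq) for seq in dataset.alignment.sequences])
    good = codes < 4
    d = np.zeros((n, n))
    n_sites = np.zeros((n, n), dtype=int)
    np.fill_diagonal(n_sites, int(dataset.alignment.length))
    for i in range(n):
        n_sites[i, i] = int(good[i].sum())
        for j in range(i + 1, n):
            comparable = good[i] & good[j]
            ns = int(comparable.sum())
            n_sites[i, j] = n_sites[j, i] = ns
            try:
                if ns == 0:
                    raise IncomparablePairError(
                        f"no comparable columns for pair ({ids[i]!r}, {ids[j]!r})"
                    )
                diff = comparable & (codes[i] != codes[j])
                ts = int((diff & ((codes[i] & 1) == (codes[j] & 1))).sum())
                tv = int(diff.sum()) - ts
                dij = k2p_distance(
                    SitePairCounts(n_sites=ns, n_transitions=ts, n_transversions=tv)
                )
            except (SaturationError, IncomparablePairError) as exc:
                if on_saturation == "raise":
                    raise type(exc)(
                        f"pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                    ) from None
                logger.warning(
                    "pair (%s, %s) excluded as missing: %s", ids[i], ids[j], exc
                )
                dij = math.nan
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=tuple(ids), d=d, n_sites=n_sites)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square TSV with specimen IDs as header row and column."""
    df = pd.DataFrame(dm.d, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t", index_label="specimen_id", float_format="%.12g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square TSV distance matrix written by :func:`write_distance_matrix`.

    Comparable-site counts are not stored in the TSV and are filled with -1
    (unknown).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise ValueError("distance-matrix TSV rows and columns disagree")
    d = df.to_numpy(dtype=float)
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance-matrix TSV is not symmetric")
    return DistanceMatrix(ids=ids, d=d, n_sites=np.full_like(d, -1, dtype=int))
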