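"""Reading, validating and joining aligned FASTA matrices and specimen metadata.

The analyses in this package consume a :class:`BarcodeDataset`: an aligned
nucleotide matrix (equal-length rows, IUPAC alphabet plus gap) joined
one-to-one with a specimen-metadata table carrying a morphospecies label per
specimen.  Alignment is an input contract — unaligned input is an error,
never silently re-aligned.

Conventions
-----------
* Sequences are normalised to upper case on read and ``U`` is mapped to
  ``T`` (COI barcodes circulate in both conventions).
* The specimen ID is the first whitespace-delimited token of the FASTA
  header; the remainder of the header is ignored.  Species labels live in
  the metadata table, never in headers.
* Columns are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import collections
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    AlphabetError,
    DegenerateInputError,
    JoinError,
    MetadataError,
)

#: Accepted characters after upper-casing and U->T mapping: the four bases,
#: IUPAC ambiguity codes, N and the gap character.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Characters counted as unambiguous bases.
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SpecimenRecord:
    """One row of the specimen-metadata table.

    Parameters
    ----------
    specimen_id:
        Unique specimen identifier (e.g. a BOLD process ID or accession).
    species_label:
        Morphospecies assignment (a binomial in real data).
    locality:
        Optional sampling locality.
    outgroup:
        When true the specimen is excluded from distance-based analyses by
        default (outgroups belong in tree inference, not in the barcode-gap
        statistics).
    """

    specimen_id: str
    species_label: str
    locality: str | None = None
    outgroup: bool = False

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if not self.species_label:
            raise MetadataError(
                f"species_label must be non-empty (specimen {self.specimen_id!r})"
            )


@dataclass(frozen=True)
class AlignedMatrix:
    """Equal-length nucleotide rows keyed by specimen ID."""

    records: tuple[tuple[str, str], ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError(
                f"an aligned matrix needs at least 2 records, got {len(self.records)}"
            )
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            by_len = collections.defaultdict(list)
            for sid, seq in self.records:
                by_len[len(seq)].append(sid)
            detail = "; ".join(
                f"length {n}: {', '.join(ids)}" for n, ids in sorted(by_len.items())
            )
            raise AlignmentError(f"sequences are not aligned (unequal lengths): {detail}")
        (length,) = lengths
        if length == 0:
            raise AlignmentError("aligned matrix has zero columns")
        object.__setattr__(self, "length", length)
        seen: set[str] = set()
        for sid, seq in self.records:
            if not sid:
                raise AlignmentError("empty specimen ID in alignment")
            if sid in seen:
                raise AlignmentError(f"duplicate specimen ID in alignment: {sid!r}")
            seen.add(sid)
            for col, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {col + 1}"
                    )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence(self, specimen_id: str) -> str:
        for sid, seq in self.records:
            if sid == specimen_id:
                return seq
        raise KeyError(specimen_id)


@dataclass(frozen=True)
class BarcodeDataset:
    """An aligned matrix joined one-to-one with specimen metadata."""

    alignment: AlignedMatrix
    metadata: tuple[SpecimenRecord, ...]

    def __post_init__(self) -> None:
        align_ids = set(self.alignment.ids)
        meta_ids = [r.specimen_id for r in self.metadata]
        if len(meta_ids) != len(set(meta_ids)):
            dupes = [i for i, c in collections.Counter(meta_ids).items() if c > 1]
            raise MetadataError(f"duplicate specimen IDs in metadata: {sorted(dupes)}")
        only_align = sorted(align_ids - set(meta_ids))
        only_meta = sorted(set(meta_ids) - align_ids)
        if only_align or only_meta:
            raise JoinError(
                "alignment and metadata IDs do not match; "
                f"alignment-only: {only_align}; metadata-only: {only_meta}"
            )

    @property
    def ids(self) -> tuple[str, ...]:
        """Specimen IDs in alignment order."""
        return self.alignment.ids

    @property
    def labels(self) -> dict[str, str]:
        """Mapping specimen ID -> morphospecies label."""
        return {r.specimen_id: r.species_label for r in self.metadata}

    @property
    def n_specimens(self) -> int:
        return len(self.alignment.records)

    def record(self, specimen_id: str) -> SpecimenRecord:
        for r in self.metadata:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def without_outgroups(self) -> "BarcodeDataset":
        """Drop specimens flagged as outgroup (default for distance analyses)."""
        keep = {r.specimen_id for r in self.metadata if not r.outgroup}
        if keep == set(self.ids):
            return self
        return BarcodeDataset(
            alignment=AlignedMatrix(
                tuple((sid, seq) for sid, seq in self.alignment.records if sid in keep)
            ),
            metadata=tuple(r for r in self.metadata if not r.outgroup),
        )


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedMatrix:
    """Read an aligned multi-record FASTA into an :class:`AlignedMatrix`.

    The first whitespace-delimited header token becomes the specimen ID.
    Raises :class:`AlignmentError` on unequal lengths and
    :class:`AlphabetError` on characters outside the IUPAC alphabet.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = [
        (rec.id, _normalise(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return AlignedMatrix(tuple(records))


def write_alignment(matrix: AlignedMatrix, path: str | Path) -> None:
    """Write an aligned matrix as multi-record FASTA (round-trip safe)."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in matrix.records
    ]
    SeqIO.write(recs, str(path), "fasta")


_REQUIRED_COLUMNS = ("specimen_id", "species_label")


def read_metadata(path: str | Path) -> tuple[SpecimenRecord, ...]:
    """Read a specimen-metadata table (TSV or CSV, sniffed from the header).

    Required columns: ``specimen_id`` and ``species_label``; optional:
    ``locality`` and boolean ``outgroup``.  Duplicate IDs are rejected.
    """
    text = Path(path).read_text(encoding="utf-8")
    header = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(_stdio.StringIO(text), sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise MetadataError(f"metadata table {path} is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table {path} lacks required columns: {missing}")
    if df.empty:
        raise MetadataError(f"metadata table {path} has a header but no rows")
    ids = df["specimen_id"].tolist()
    dupes = sorted(i for i, c in collections.Counter(ids).items() if c > 1)
    if dupes:
        raise MetadataError(f"duplicate specimen IDs in metadata: {dupes}")
    records = []
    for _, row in df.iterrows():
        loc = row.get("locality")
        loc = None if (loc is None or pd.isna(loc)) else str(loc)
        out = row.get("outgroup")
        outgroup = (not pd.isna(out)) and str(out).strip().lower() in {
            "1", "true", "yes",
        } if out is not None else False
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species_label=str(row["species_label"]),
                locality=loc,
                outgroup=bool(outgroup),
            )
        )
    return tuple(records)


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write specimen metadata as a TSV readable by :func:`read_metadata`."""
    rows = [
        {
            "specimen_id": r.specimen_id,
            "species_label": r.species_label,
            "locality": "" if r.locality is None else r.locality,
            "outgroup": "true" if r.outgroup else "false",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_dataset(
    alignment: AlignedMatrix, metadata: Sequence[SpecimenRecord]
) -> BarcodeDataset:
    """Join alignment and metadata into an analysis-ready dataset.

    Raises :class:`JoinError` listing IDs present on exactly one side.
    """
    return BarcodeDataset(alignment=alignment, metadata=tuple(metadata))


def base_composition(alignment: AlignedMatrix) -> dict[str, float]:
    """Proportions of A, C, G and T over all unambiguous bases.

    Gaps, N and ambiguity codes are excluded from both numerator and
    denominator.  Raises :class:`DegenerateInputError` if the alignment
    contains no unambiguous base at all.
    """
    counts = collections.Counter()
    for _, seq in alignment.records:
        counts.update(seq)
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise DegenerateInputError(
            "alignment contains no unambiguous A/C/G/T base"
        )
    return {b: counts[b] / total for b in BASES}
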