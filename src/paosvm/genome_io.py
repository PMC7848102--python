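"""Readers, writers and splicing for the formats the pipeline touches.

Covers multi-FASTA genome segments (optionally gzip-compressed),
tab-separated label tables, tab-separated similarity matrices, and the
splicing step that joins an organism's genome segments into one
long-chain sequence for alignment-free comparison.

Coordinate convention: 0-based, half-open, everywhere.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

if TYPE_CHECKING:  # pragma: no cover - import cycle guard (sketch_align imports Genome)
    from .sketch_align import SimilarityMatrix

__all__ = [
    "GenomeIOError",
    "SequenceRecord",
    "Genome",
    "LabelTable",
    "read_fasta",
    "write_fasta",
    "splice_segments",
    "read_labels",
    "write_labels",
    "read_matrix",
    "write_matrix",
]

_ALPHABET = frozenset("ACGTN")


class GenomeIOError(ValueError):
    """Raised for malformed inputs; the message names the offending record."""


def _normalize(sequence: str, *, context: str) -> str:
    """Uppercase, map U->T, reject anything outside {A,C,G,T,N}."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise GenomeIOError(
            f"{context}: illegal character {seq[pos]!r} at sequence position {pos} "
            "(only A, C, G, T, N, U accepted)"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry, stored uppercase over {A,C,G,T,N}.

    ``organism_id`` defaults to the part of ``id`` before the first ``|``,
    the convention used by the splicing step to group segments of one
    organism; pass it explicitly to override.
    """

    id: str
    sequence: str
    organism_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("record with empty id")
        if not self.sequence:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", _normalize(self.sequence, context=f"record {self.id!r}"))
        if not self.organism_id:
            object.__setattr__(self, "organism_id", self.id.split("|", 1)[0])

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """A spliced long-chain genome for one organism.

    ``segment_boundaries`` are 0-based half-open intervals covering the
    non-spacer portions of ``sequence``, in splicing order.
    """

    organism_id: str
    sequence: str
    n_segments: int
    segment_boundaries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segment_boundaries:
            if not (0 <= start < end <= len(self.sequence)):
                raise GenomeIOError(
                    f"genome {self.organism_id!r}: boundary ({start}, {end}) outside "
                    f"[0, {len(self.sequence)})"
                )
            if start < prev_end:
                raise GenomeIOError(f"genome {self.organism_id!r}: overlapping segment boundaries")
            prev_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, organism_id: str, sequence: str) -> "Genome":
        """Wrap a single contiguous sequence as a one-segment genome."""
        seq = _normalize(sequence, context=f"genome {organism_id!r}")
        return cls(organism_id, seq, 1, ((0, len(seq)),))


@dataclass(frozen=True)
class LabelTable:
    """organism_id -> label; 1 = known PAO, 0 = not confirmed a PAO."""

    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        for org, label in self.mapping.items():
            if label not in (0, 1):
                raise GenomeIOError(f"label for {org!r} is {label!r}, expected 0 or 1")

    def __getitem__(self, organism_id: str) -> int:
        return self.mapping[organism_id]

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, organism_id: str) -> bool:
        return organism_id in self.mapping

    def positives(self) -> list[str]:
        return [o for o, v in self.mapping.items() if v == 1]

    def unknowns(self) -> list[str]:
        return [o for o, v in self.mapping.items() if v == 0]


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) multi-FASTA file into normalized records.

    An empty file yields an empty list. Duplicate ids, empty sequence
    bodies and characters outside {A,C,G,T,N,U} raise :class:`GenomeIOError`
    naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        text_peek = handle.read(1)
        handle.seek(0)
        if text_peek and text_peek != ">":
            raise GenomeIOError(f"{path}: malformed FASTA, first byte is {text_peek!r} not '>'")
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise GenomeIOError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(entry.id)
            if len(entry.seq) == 0:
                raise GenomeIOError(f"{path}: record {entry.id!r} has an empty sequence body")
            records.append(SequenceRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def splice_segments(segments: Sequence[SequenceRecord], spacer_length: int = 15) -> Genome:
    """Concatenate one organism's segments into a single long-chain genome.

    Segments are joined in lexicographic order of segment id with a run of
    ``spacer_length`` ``N`` characters between consecutive segments, so no
    k-mer with k <= spacer_length can span a join (N-containing k-mers are
    never sketched downstream).
    """
    if not segments:
        raise GenomeIOError("splice_segments: empty segment list")
    if spacer_length < 0:
        raise GenomeIOError("splice_segments: spacer_length must be non-negative")
    organisms = {s.organism_id for s in segments}
    if len(organisms) != 1:
        raise GenomeIOError(f"splice_segments: mixed organism ids {sorted(organisms)}")
    ordered = sorted(segments, key=lambda s: s.id)
    parts: list[str] = []
    boundaries: list[tuple[int, int]] = []
    offset = 0
    spacer = "N" * spacer_length
    for i, seg in enumerate(ordered):
        if i > 0:
            parts.append(spacer)
            offset += spacer_length
        parts.append(seg.sequence)
        boundaries.append((offset, offset + len(seg)))
        offset += len(seg)
    return Genome(
        organism_id=organisms.pop(),
        sequence="".join(parts),
        n_segments=len(ordered),
        segment_boundaries=tuple(boundaries),
    )


def read_labels(path: str | Path) -> LabelTable:
    """Read a tab-separated (organism_id, label) table; labels must be 0/1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["organism_id", "label"], dtype=str)
    if len(df) and df.iloc[0, 0] == "organism_id":
        df = df.iloc[1:]
    mapping: dict[str, int] = {}
    for org, raw in zip(df["organism_id"], df["label"]):
        if org in mapping:
            raise GenomeIOError(f"{path}: duplicate organism id {org!r}")
        try:
            label = int(raw)
        except (TypeError, ValueError):
            raise GenomeIOError(f"{path}: label for {org!r} is {raw!r}, expected 0 or 1") from None
        if label not in (0, 1):
            raise GenomeIOError(f"{path}: label for {org!r} is {label}, expected 0 or 1")
        mapping[org] = label
    return LabelTable(mapping)


def write_labels(labels: LabelTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"organism_id": list(labels.mapping), "label": list(labels.mapping.values())}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def write_matrix(matrix: "SimilarityMatrix", path: str | Path) -> None:
    """Write a similarity matrix as TSV with an id header row and column."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="organism_id")


def read_matrix(path: str | Path) -> "SimilarityMatrix":
    """Read a TSV similarity matrix; header ids must match the index column."""
    from .sketch_align import SimilarityMatrix  # deferred: sketch_align imports Genome

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if df.shape[0] != df.shape[1]:
        raise GenomeIOError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square")
    if ids != row_ids:
        raise GenomeIOError(f"{path}: header ids do not match row ids")
    return SimilarityMatrix(ids=ids, values=df.to_numpy(dtype=float))
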