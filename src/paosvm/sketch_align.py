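"""Alignment-free all-vs-all genome similarity from minimizer sketches.

A genome is summarized by its set of (w, k)-minimizers: within every
window of ``w`` consecutive N-free k-mers, the k-mer whose hashed
canonical form is minimal is kept (ties keep every tied k-mer). The
similarity of two genomes is the containment of the smaller sketch in
the larger one:

    sim(A, B) = |M_A intersect M_B| / min(|M_A|, |M_B|)

which is robust to genome-length asymmetry: a small genome fully
contained in a large one scores 1 regardless of the size ratio.

Alternatively, overlap records produced by an external all-vs-all
aligner (PAF format, as emitted by minimap2) can be converted to the
same [0, 1] scale by projecting alignment blocks onto the shorter
genome of each pair and measuring the covered fraction.

The k-mer hash is a fixed invertible 64-bit mix (splitmix64 finalizer)
seeded by :data:`DEFAULT_HASH_SEED`, so identical inputs give identical
sketches across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import Genome, GenomeIOError

__all__ = [
    "DEFAULT_K",
    "DEFAULT_W",
    "DEFAULT_HASH_SEED",
    "SketchParams",
    "Sketch",
    "SimilarityMatrix",
    "PafRecord",
    "canonical_kmer",
    "hash_kmer_codes",
    "minimizer_sketch",
    "containment_similarity",
    "read_paf",
    "paf_similarity",
    "all_vs_all",
]

DEFAULT_K = 15
DEFAULT_W = 10
DEFAULT_HASH_SEED = 0x9E3779B97F4A7C15

_MASK64 = (1 << 64) - 1
# base encoding A=0 C=1 G=2 T=3 makes numeric order equal lexicographic order
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_DECODE = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SketchError(ValueError):
    pass


@dataclass(frozen=True)
class SketchParams:
    """Minimizer parameters: k-mer length, window length (in k-mers), hash seed."""

    k: int = DEFAULT_K
    w: int = DEFAULT_W
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if self.k < 3:
            raise SketchError(f"k must be >= 3, got {self.k}")
        if self.w < 1:
            raise SketchError(f"w must be >= 1, got {self.w}")


@dataclass(frozen=True)
class Sketch:
    """The distinct (hash, canonical k-mer) minimizers of one genome."""

    organism_id: str
    minimizers: frozenset[tuple[int, str]]
    genome_length: int
    params: SketchParams

    def __len__(self) -> int:
        return len(self.minimizers)


@dataclass
class SimilarityMatrix:
    """Symmetric N x N organism-by-organism similarity with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise SketchError("duplicate organism ids in similarity matrix")
        if self.values.shape != (n, n):
            raise SketchError(f"matrix shape {self.values.shape} does not match {n} ids")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise SketchError("similarity values outside [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise SketchError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise SketchError("similarity matrix diagonal is not 1")
        self._index = {org: i for i, org in enumerate(self.ids)}

    def index_of(self, organism_id: str) -> int:
        try:
            return self._index[organism_id]
        except KeyError:
            raise SketchError(f"unknown organism id {organism_id!r}") from None

    def row(self, organism_id: str) -> np.ndarray:
        return self.values[self.index_of(organism_id)].copy()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    kmer = kmer.upper()
    if set(kmer) - set("ACGT"):
        raise SketchError(f"k-mer {kmer!r} contains non-ACGT characters; skip such k-mers")
    rc = _revcomp(kmer)
    return kmer if kmer <= rc else rc


def hash_kmer_codes(codes: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Invertible 64-bit mix (splitmix64 finalizer) of 2-bit k-mer codes."""
    x = np.asarray(codes, dtype=np.uint64) ^ np.uint64(seed & _MASK64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _decode_code(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_DECODE[(code >> shift) & 3])
    return "".join(out)


def minimizer_sketch(genome: Genome, params: SketchParams | None = None) -> Sketch:
    """Select the distinct canonical minimizers of a genome.

    Every window of ``w`` consecutive valid (N-free) k-mers contributes the
    k-mer(s) of minimal hash; k-mers containing N never enter a window, so
    splice spacers of length >= k contribute nothing. A genome shorter than
    k (or with no run of w valid k-mers) yields an empty sketch.
    """
    params = params or SketchParams()
    k, w = params.k, params.w
    seq = genome.sequence
    empty = Sketch(genome.organism_id, frozenset(), len(seq), params)
    if len(seq) < k:
        return empty
    base = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    windows = sliding_window_view(base, k)
    valid = (windows < 4).all(axis=1)
    if not valid.any():
        return empty
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    as_int = windows.astype(np.int64)
    fwd = as_int @ pw
    rc = (3 - as_int) @ pw[::-1]
    canon = np.minimum(fwd, rc).astype(np.uint64)
    hashes = hash_kmer_codes(canon, params.hash_seed)

    selected: list[np.ndarray] = []
    valid_idx = np.flatnonzero(valid)
    run_breaks = np.flatnonzero(np.diff(valid_idx) > 1)
    for run in np.split(valid_idx, run_breaks + 1):
        if run.size < w:
            continue
        run_hashes = hashes[run]
        win = sliding_window_view(run_hashes, w)
        win_min = win.min(axis=1)
        w_idx, offset = np.nonzero(win == win_min[:, None])  # ties keep every tied k-mer
        selected.append(run[w_idx + offset])
    if not selected:
        return empty
    positions = np.unique(np.concatenate(selected))
    codes = np.unique(canon[positions])
    code_hashes = hash_kmer_codes(codes, params.hash_seed)
    minimizers = frozenset(
        (int(h), _decode_code(int(c), k)) for c, h in zip(codes, code_hashes)
    )
    return Sketch(genome.organism_id, minimizers, len(seq), params)


def containment_similarity(a: Sketch, b: Sketch) -> float:
    """Shared-minimizer fraction of the smaller sketch, in [0, 1]."""
    if a.params != b.params:
        raise SketchError(
            f"sketch parameter mismatch between {a.organism_id!r} and {b.organism_id!r}"
        )
    if not a.minimizers and not b.minimizers:
        return 1.0 if a.organism_id == b.organism_id else 0.0
    if not a.minimizers or not b.minimizers:
        return 0.0
    inter = len(a.minimizers & b.minimizers)
    return inter / min(len(a.minimizers), len(b.minimizers))


@dataclass(frozen=True)
class PafRecord:
    """One PAF overlap line (columns 1-12)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int

    def swapped(self) -> "PafRecord":
        """The same overlap with query and target roles exchanged."""
        return PafRecord(
            self.target_name, self.target_length, self.target_start, self.target_end,
            self.strand, self.query_name, self.query_length, self.query_start,
            self.query_end, self.residue_matches, self.block_length, self.mapping_quality,
        )


def read_paf(path: str | Path) -> list[PafRecord]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise GenomeIOError(f"{path}:{lineno}: PAF line has {len(cols)} columns, need >= 12")
            records.append(
                PafRecord(
                    cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4],
                    cols[5], int(cols[6]), int(cols[7]), int(cols[8]),
                    int(cols[9]), int(cols[10]), int(cols[11]),
                )
            )
    return records


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
        last_end = max(last_end, end)
    return total


def paf_similarity(
    records: Sequence[PafRecord], query_length: int, target_length: int
) -> float:
    """Fraction of the shorter genome covered by the union of overlap blocks."""
    on_query = query_length <= target_length
    shorter = min(query_length, target_length)
    intervals = []
    for rec in records:
        start, end, length = (
            (rec.query_start, rec.query_end, query_length)
            if on_query
            else (rec.target_start, rec.target_end, target_length)
        )
        if end < start:
            raise GenomeIOError(
                f"PAF record {rec.query_name}->{rec.target_name}: negative interval ({start}, {end})"
            )
        if start < 0 or end > length:
            raise GenomeIOError(
                f"PAF record {rec.query_name}->{rec.target_name}: coordinates ({start}, {end}) "
                f"exceed genome length {length}"
            )
        intervals.append((start, end))
    if shorter == 0:
        return 0.0
    return min(1.0, _interval_union_length(intervals) / shorter)


def all_vs_all(
    sketches: Sequence[Sketch],
    backend: str = "native",
    paf_path: str | Path | None = None,
) -> SimilarityMatrix:
    """All-vs-all similarity over a panel of sketches.

    Each unordered pair is computed once and mirrored; the diagonal is
    forced to 1. The ``paf`` backend converts externally computed overlap
    records to similarities using the sketches only for ids and lengths.
    """
    ids = [s.organism_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise SketchError("duplicate organism ids in sketch panel")
    n = len(ids)
    values = np.eye(n)
    if backend == "native":
        params = {s.params for s in sketches}
        if len(params) > 1:
            raise SketchError("sketches in a panel must share parameters")
        sets = [s.minimizers for s in sketches]
        sizes = [len(m) for m in sets]
        for i in range(n):
            for j in range(i + 1, n):
                if sizes[i] and sizes[j]:
                    sim = len(sets[i] & sets[j]) / min(sizes[i], sizes[j])
                else:
                    sim = containment_similarity(sketches[i], sketches[j])
                values[i, j] = values[j, i] = sim
    elif backend == "paf":
        if paf_path is None:
            raise SketchError("paf backend requires paf_path")
        lengths = {s.organism_id: s.genome_length for s in sketches}
        pairs: dict[tuple[str, str], list[PafRecord]] = {}
        for rec in read_paf(paf_path):
            for name in (rec.query_name, rec.target_name):
                if name not in lengths:
                    raise SketchError(f"PAF references unknown organism id {name!r}")
            if rec.query_name == rec.target_name:
                continue  # self-hits do not inform the pair similarity
            key = tuple(sorted((rec.query_name, rec.target_name)))
            oriented = rec if rec.query_name == key[0] else rec.swapped()
            pairs.setdefault(key, []).append(oriented)
        index = {org: i for i, org in enumerate(ids)}
        for (qa, qb), recs in pairs.items():
            sim = paf_similarity(recs, lengths[qa], lengths[qb])
            i, j = index[qa], index[qb]
            values[i, j] = values[j, i] = sim
    else:
        raise SketchError(f"unknown backend {backend!r}; use 'native' or 'paf'")
    return SimilarityMatrix(ids=ids, values=values)
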