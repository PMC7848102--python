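"""Per-organism feature vectors and labeled training sets.

An organism's feature vector is simply its row of the all-vs-all
similarity matrix: its similarity to every organism of the reference
panel, in panel order. The panel already provides a high-dimensional
representation, so no dimensionality reduction or rescaling is applied
(values are already in [0, 1]); the self-similarity coordinate (1 for
panel members) is retained by default and can be dropped via
``drop_self``.

Balanced training sets pair the known positives with an equally sized
uniform sample of the unlabeled pool treated as class 0 at face value —
a deliberately noisy negative class, since some unlabeled organisms may
in truth be positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIOError, LabelTable
from .sketch_align import Sketch, SimilarityMatrix, containment_similarity

__all__ = [
    "FeatureVector",
    "TrainingSet",
    "feature_vector",
    "embed_new_genome",
    "sample_negatives",
    "assemble",
    "write_training_set",
    "read_training_set",
]


@dataclass(frozen=True)
class FeatureVector:
    organism_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrainingSet:
    """Feature matrix X (rows in ``ids`` order) with labels y in {0, 1}."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.ids) != self.X.shape[0] or len(self.ids) != self.y.shape[0]:
            raise GenomeIOError("training set ids, X and y must have equal lengths")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise GenomeIOError("training labels must be in {0, 1}")

    def __len__(self) -> int:
        return len(self.ids)


def feature_vector(
    matrix: SimilarityMatrix, organism_id: str, drop_self: bool = False
) -> FeatureVector:
    """The organism's similarity-to-panel row, in matrix id order."""
    row = matrix.row(organism_id)
    if drop_self:
        row = np.delete(row, matrix.index_of(organism_id))
    return FeatureVector(organism_id, row)


def embed_new_genome(sketch: Sketch, reference_sketches: Sequence[Sketch]) -> FeatureVector:
    """Similarity of an out-of-panel genome to each reference, in panel order.

    For a genome already in the panel this reproduces its matrix row.
    """
    for ref in reference_sketches:
        if ref.params != sketch.params:
            raise GenomeIOError(
                f"sketch params of {sketch.organism_id!r} do not match reference "
                f"{ref.organism_id!r}"
            )
    values = np.array(
        [containment_similarity(sketch, ref) for ref in reference_sketches], dtype=float
    )
    return FeatureVector(sketch.organism_id, values)


def sample_negatives(unlabeled_ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform sample without replacement from the unlabeled pool."""
    if n > len(unlabeled_ids):
        raise GenomeIOError(
            f"cannot sample {n} negatives from a pool of {len(unlabeled_ids)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(unlabeled_ids), size=n, replace=False)
    return [unlabeled_ids[i] for i in picked]


def assemble(
    matrix: SimilarityMatrix,
    labels: LabelTable | None,
    positive_ids: Sequence[str],
    negative_ids: Sequence[str],
) -> TrainingSet:
    """Stack labeled feature vectors: y=1 for positives, y=0 for negatives.

    If ``labels`` is given, every positive id must carry label 1 in it
    (negatives may be unlabeled organisms pressed into class 0).
    """
    overlap = set(positive_ids) & set(negative_ids)
    if overlap:
        raise GenomeIOError(f"ids in both classes: {sorted(overlap)[:5]}")
    if not positive_ids or not negative_ids:
        raise GenomeIOError("both classes must be non-empty before fitting")
    if labels is not None:
        mislabeled = [o for o in positive_ids if o in labels and labels[o] != 1]
        if mislabeled:
            raise GenomeIOError(f"positive ids labeled 0 in the label table: {mislabeled[:5]}")
    ids = list(positive_ids) + list(negative_ids)
    X = np.stack([matrix.row(org) for org in ids])
    y = np.array([1] * len(positive_ids) + [0] * len(negative_ids), dtype=int)
    return TrainingSet(ids=ids, X=X, y=y)


def write_training_set(data: TrainingSet, path: str | Path) -> None:
    df = pd.DataFrame(data.X)
    df.insert(0, "organism_id", data.ids)
    df.insert(1, "label", data.y)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_training_set(path: str | Path) -> TrainingSet:
    df = pd.read_csv(path, sep="\t")
    return TrainingSet(
        ids=[str(i) for i in df["organism_id"]],
        X=df.drop(columns=["organism_id", "label"]).to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
    )
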