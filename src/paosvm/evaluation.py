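"""Doubly stratified 10-fold cross-validation and candidate ranking.

The labeled panel (known PAOs vs unlabeled organisms treated as class 0)
is first dealt into ``n_parts`` parts, stratified by class: each class
is shuffled with a seeded generator and dealt round-robin, so per-class
part sizes differ by at most one (1,833 positives over 10 parts gives
183-184 each; 4,485 unknowns gives 448-449). The default "nested"
scheme then splits each part into ``n_groups`` groups the same way
(18-19 / 44-45 at full scale), trains on nine seeded-randomly-chosen
groups and tests on the held-out group, yielding one accuracy per part.
The "parts" scheme is the standard k-fold rotation instead: train on
the other parts, test on the held-out part — usable when parts are too
small to split into groups.

Candidate screening scores every organism outside the training pool
with the fitted decision function and ranks them by decision value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import linear_svm as svm
from .sketch_align import SimilarityMatrix

__all__ = [
    "Part",
    "CVReport",
    "CandidateList",
    "partition_stratified",
    "split_groups",
    "part_cv_accuracy",
    "summarize_cv",
    "cross_validate",
    "predict_candidates",
]


@dataclass(frozen=True)
class Part:
    """One stratified part: its positives, its unknowns, and a 1-based index."""

    index: int
    positive_ids: tuple[str, ...]
    unknown_ids: tuple[str, ...]


@dataclass
class CVReport:
    per_part_accuracy: list[float]
    mean_accuracy: float
    std_accuracy: float
    seed: int
    n_parts: int
    n_groups: int
    scheme: str
    svm_config: svm.SVMConfig

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "part": range(1, len(self.per_part_accuracy) + 1),
                "accuracy": self.per_part_accuracy,
            }
        )
        with open(path, "w") as handle:
            handle.write(f"# scheme={self.scheme} n_parts={self.n_parts} ")
            handle.write(f"n_groups={self.n_groups} seed={self.seed} C={self.svm_config.C}\n")
            handle.write(f"# mean={self.mean_accuracy:.4f} std={self.std_accuracy:.4f}\n")
            df.to_csv(handle, sep="\t", index=False)


@dataclass
class CandidateList:
    """Organisms ranked by decision value, most PAO-like first."""

    records: list[tuple[str, float, int]]  # (organism_id, decision_value, predicted_label)

    def __post_init__(self) -> None:
        dv = [r[1] for r in self.records]
        if any(dv[i] < dv[i + 1] for i in range(len(dv) - 1)):
            raise ValueError("candidate records must be sorted by decision value descending")

    def __len__(self) -> int:
        return len(self.records)

    def predicted_positive(self) -> list[str]:
        return [org for org, _, label in self.records if label == 1]

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.records, columns=["organism_id", "decision_value", "predicted_label"])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _deal(ids: Sequence[str], n_bins: int, rng: np.random.Generator) -> list[list[str]]:
    """Seeded shuffle then round-robin deal; bin sizes differ by at most 1."""
    shuffled = list(ids)
    rng.shuffle(shuffled)
    return [shuffled[i::n_bins] for i in range(n_bins)]


def partition_stratified(
    positive_ids: Sequence[str],
    unknown_ids: Sequence[str],
    n_parts: int = 10,
    seed: int = 0,
) -> list[Part]:
    """Deal each class round-robin into ``n_parts`` stratified parts."""
    if n_parts < 2:
        raise ValueError(f"n_parts must be >= 2, got {n_parts}")
    for name, ids in (("positive", positive_ids), ("unknown", unknown_ids)):
        if len(ids) < n_parts:
            raise ValueError(
                f"{name} class has {len(ids)} members, fewer than n_parts={n_parts}"
            )
    rng = np.random.default_rng(seed)
    pos_bins = _deal(positive_ids, n_parts, rng)
    unk_bins = _deal(unknown_ids, n_parts, rng)
    return [
        Part(index=i + 1, positive_ids=tuple(p), unknown_ids=tuple(u))
        for i, (p, u) in enumerate(zip(pos_bins, unk_bins))
    ]


def split_groups(part: Part, n_groups: int = 10, seed: int = 0) -> list[Part]:
    """Stratified round-robin deal of one part into groups."""
    if len(part.positive_ids) < n_groups or len(part.unknown_ids) < n_groups:
        raise ValueError(
            f"part {part.index}: classes of sizes {len(part.positive_ids)}/"
            f"{len(part.unknown_ids)} cannot be split into {n_groups} groups"
        )
    rng = np.random.default_rng(seed)
    pos_bins = _deal(part.positive_ids, n_groups, rng)
    unk_bins = _deal(part.unknown_ids, n_groups, rng)
    return [
        Part(index=i + 1, positive_ids=tuple(p), unknown_ids=tuple(u))
        for i, (p, u) in enumerate(zip(pos_bins, unk_bins))
    ]


def _accuracy_on(
    model: svm.SVMModel, matrix: SimilarityMatrix, pos_ids: Sequence[str], unk_ids: Sequence[str]
) -> float:
    ids = list(pos_ids) + list(unk_ids)
    truth = np.array([1] * len(pos_ids) + [0] * len(unk_ids))
    X = np.stack([matrix.row(org) for org in ids])
    pred = (svm.decision_values(model, X) >= 0).astype(int)
    return float(np.mean(pred == truth))


def part_cv_accuracy(
    part: Part,
    matrix: SimilarityMatrix,
    svm_config: svm.SVMConfig | None = None,
    seed: int = 0,
    n_groups: int = 10,
    rotation: str = "single",
) -> float:
    """Within-part accuracy: train on all groups but one, test on the held-out one.

    ``rotation="single"`` (default) picks the held-out group seeded-randomly
    and returns that one accuracy; ``rotation="full"`` averages over all
    ``n_groups`` hold-outs.
    """
    svm_config = svm_config or svm.SVMConfig()
    rng = np.random.default_rng(seed)
    groups = split_groups(part, n_groups=n_groups, seed=int(rng.integers(2**31)))
    if rotation == "single":
        test_indices = [int(rng.integers(n_groups))]
    elif rotation == "full":
        test_indices = list(range(n_groups))
    else:
        raise ValueError(f"rotation must be 'single' or 'full', got {rotation!r}")
    accs = []
    for test_idx in test_indices:
        train_pos = [o for g in groups for o in g.positive_ids if g.index != test_idx + 1]
        train_unk = [o for g in groups for o in g.unknown_ids if g.index != test_idx + 1]
        test = groups[test_idx]
        try:
            model = svm.fit(feat.assemble(matrix, None, train_pos, train_unk), svm_config)
        except (ValueError, svm.ConvergenceError) as err:
            raise RuntimeError(f"part {part.index}: {err}") from err
        accs.append(_accuracy_on(model, matrix, test.positive_ids, test.unknown_ids))
    return float(np.mean(accs))


def summarize_cv(accuracies: Sequence[float], ddof: int = 1) -> tuple[float, float]:
    """Arithmetic mean and standard deviation (sample, divisor n-1, by default)."""
    if len(accuracies) == 0:
        raise ValueError("cannot summarize an empty accuracy list")
    arr = np.asarray(accuracies, dtype=float)
    std = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
    return float(arr.mean()), std


def cross_validate(
    matrix: SimilarityMatrix,
    positive_ids: Sequence[str],
    unknown_ids: Sequence[str],
    n_parts: int = 10,
    n_groups: int = 10,
    scheme: str = "nested",
    svm_config: svm.SVMConfig | None = None,
    seed: int = 0,
    rotation: str = "single",
) -> CVReport:
    """Run the full stratified CV and summarize per-part accuracies."""
    svm_config = svm_config or svm.SVMConfig()
    rng = np.random.default_rng(seed)
    parts = partition_stratified(positive_ids, unknown_ids, n_parts, int(rng.integers(2**31)))
    accs: list[float] = []
    if scheme == "nested":
        for part in parts:
            accs.append(
                part_cv_accuracy(
                    part, matrix, svm_config, seed=int(rng.integers(2**31)),
                    n_groups=n_groups, rotation=rotation,
                )
            )
    elif scheme == "parts":
        for part in parts:
            train_pos = [o for p in parts if p.index != part.index for o in p.positive_ids]
            train_unk = [o for p in parts if p.index != part.index for o in p.unknown_ids]
            model = svm.fit(feat.assemble(matrix, None, train_pos, train_unk), svm_config)
            accs.append(_accuracy_on(model, matrix, part.positive_ids, part.unknown_ids))
    else:
        raise ValueError(f"scheme must be 'nested' or 'parts', got {scheme!r}")
    mean, std = summarize_cv(accs)
    return CVReport(
        per_part_accuracy=accs,
        mean_accuracy=mean,
        std_accuracy=std,
        seed=seed,
        n_parts=n_parts,
        n_groups=n_groups,
        scheme=scheme,
        svm_config=svm_config,
    )


def predict_candidates(
    model: svm.SVMModel,
    matrix: SimilarityMatrix,
    excluded_ids: Sequence[str],
) -> CandidateList:
    """Score every organism outside ``excluded_ids``, ranked most PAO-like first."""
    excluded = set(excluded_ids)
    ids = [org for org in matrix.ids if org not in excluded]
    if not ids:
        return CandidateList(records=[])
    X = np.stack([matrix.row(org) for org in ids])
    dv = svm.decision_values(model, X)
    order = sorted(range(len(ids)), key=lambda i: (-dv[i], ids[i]))
    records = [(ids[i], float(dv[i]), 1 if dv[i] >= 0 else 0) for i in order]
    return CandidateList(records=records)
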