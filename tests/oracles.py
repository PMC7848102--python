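"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (exhaustive scans, generic QP)
and stays independent of the code paths it validates.
"""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def splitmix64(value: int, seed: int) -> int:
    """Pure-python mirror of the fixed k-mer hash (shared primitive)."""
    x = (value ^ seed) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (x ^ (x >> 31)) & _MASK64


def kmer_code(kmer: str) -> int:
    code = 0
    for base in kmer:
        code = code * 4 + "ACGT".index(base)
    return code


def brute_minimizers(sequence: str, k: int, w: int, hash_seed: int) -> set[tuple[int, str]]:
    """Exhaustive window scan: every window of w consecutive valid k-mers
    contributes all k-mers achieving the minimal hash of the canonical form."""
    seq = sequence.upper()
    n_kmers = len(seq) - k + 1
    if n_kmers < 1:
        return set()
    entries: list[tuple[int, str] | None] = []
    for pos in range(n_kmers):
        kmer = seq[pos : pos + k]
        if set(kmer) <= set("ACGT"):
            canon = min(kmer, revcomp(kmer))
            entries.append((splitmix64(kmer_code(canon), hash_seed), canon))
        else:
            entries.append(None)
    selected: set[tuple[int, str]] = set()
    for start in range(n_kmers - w + 1):
        window = entries[start : start + w]
        if any(e is None for e in window):
            continue
        low = min(h for h, _ in window)
        selected.update(e for e in window if e[0] == low)
    return selected


def kmer_set_containment(seq_a: str, seq_b: str, k: int) -> float:
    """Containment of the full (unsampled) canonical k-mer sets."""

    def kset(seq: str) -> set[str]:
        out = set()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if set(kmer) <= set("ACGT"):
                out.add(min(kmer, revcomp(kmer)))
        return out

    sa, sb = kset(seq_a), kset(seq_b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    covered: set[int] = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return len(covered)


def dual_qp(X: np.ndarray, y01: np.ndarray, C: float) -> tuple[float, np.ndarray]:
    """Generic QP solution of the soft-margin dual (SLSQP); returns
    (dual objective value, multipliers)."""
    from scipy.optimize import minimize

    y = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    n = len(y)
    Q = np.outer(y, y) * (X @ X.T)

    best = None
    for start in (np.zeros(n), np.full(n, min(C, 1.0) / 2)):
        res = minimize(
            lambda a: 0.5 * a @ Q @ a - a.sum(),
            x0=start,
            jac=lambda a: Q @ a - 1.0,
            bounds=[(0.0, C)] * n,
            constraints={"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
            method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        value = -(0.5 * res.x @ Q @ res.x - res.x.sum())
        if best is None or value > best[0]:
            best = (value, res.x)
    return best
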