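from __future__ import annotations

import numpy as np
import pytest

from paosvm import sketch_align, synth


@pytest.fixture(scope="session")
def benchmark_panel():
    """The default synthetic benchmark: 5 clades x 12 genomes of 20 kb,
    2% within- vs 20% between-clade divergence, clade-pure labels on the
    first two clades. Shared across tests; treat as read-only."""
    config = synth.SimConfig(seed=2021)
    genomes, clades = synth.simulate_genomes(config)
    labels = synth.assign_labels(clades, seed=2022)
    sketches = [sketch_align.minimizer_sketch(g) for g in genomes]
    matrix = sketch_align.all_vs_all(sketches)
    return {
        "config": config,
        "genomes": genomes,
        "clades": clades,
        "labels": labels,
        "sketches": sketches,
        "matrix": matrix,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng: np.random.Generator, n: int):
    """A random valid similarity matrix over ids g00..g{n-1}."""
    values = rng.uniform(0, 1, size=(n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    return sketch_align.SimilarityMatrix(ids=[f"g{i:02d}" for i in range(n)], values=values)
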