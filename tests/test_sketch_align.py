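import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paosvm.genome_io import Genome
from paosvm.sketch_align import (
    DEFAULT_HASH_SEED,
    PafRecord,
    SketchError,
    SketchParams,
    all_vs_all,
    canonical_kmer,
    containment_similarity,
    minimizer_sketch,
    paf_similarity,
    read_paf,
)

import oracles


def _genome(seq: str, org: str = "g") -> Genome:
    return Genome.from_sequence(org, seq)


def _random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestCanonicalKmer:
    def test_palindromic_kmer_fixed(self):
        assert canonical_kmer("ACGT") == "ACGT"

    def test_reverse_complement_smaller(self):
        assert canonical_kmer("TTTT") == "AAAA"

    def test_matches_brute_force_and_idempotent(self, rng):
        for _ in range(200):
            kmer = _random_seq(rng, int(rng.integers(3, 12)))
            expected = min(kmer, oracles.revcomp(kmer))
            assert canonical_kmer(kmer) == expected
            assert canonical_kmer(canonical_kmer(kmer)) == canonical_kmer(kmer)

    def test_rejects_n(self):
        with pytest.raises(SketchError):
            canonical_kmer("ACNGT")


class TestMinimizerSketch:
    def test_too_short_sequence_gives_empty_sketch(self):
        sketch = minimizer_sketch(_genome("ACGT"), SketchParams(k=5, w=2))
        assert len(sketch) == 0

    def test_all_n_gives_empty_sketch(self):
        sketch = minimizer_sketch(_genome("N" * 50), SketchParams(k=5, w=2))
        assert len(sketch) == 0

    @pytest.mark.parametrize("k,w,length", [(5, 4, 500), (15, 10, 2000), (7, 3, 300)])
    def test_equals_exhaustive_window_scan(self, rng, k, w, length):
        seq = _random_seq(rng, length, alphabet="ACGTACGTN")  # ~11% N
        sketch = minimizer_sketch(_genome(seq), SketchParams(k=k, w=w))
        assert sketch.minimizers == oracles.brute_minimizers(seq, k, w, DEFAULT_HASH_SEED)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=120),
        k=st.integers(3, 8),
        w=st.integers(1, 5),
    )
    def test_window_scan_property(self, seq, k, w):
        sketch = minimizer_sketch(_genome("A" + seq), SketchParams(k=k, w=w))
        assert sketch.minimizers == oracles.brute_minimizers("A" + seq, k, w, DEFAULT_HASH_SEED)

    def test_strand_invariance(self, rng):
        seq = _random_seq(rng, 800)
        params = SketchParams(k=9, w=5)
        fwd = minimizer_sketch(_genome(seq), params)
        rev = minimizer_sketch(_genome(oracles.revcomp(seq)), params)
        assert fwd.minimizers == rev.minimizers

    def test_sketch_size_bounded_by_valid_windows(self, rng):
        seq = _random_seq(rng, 300)
        params = SketchParams(k=5, w=4)
        sketch = minimizer_sketch(_genome(seq), params)
        assert 0 < len(sketch) <= len(seq) - params.k + 1


class TestContainment:
    def test_identical_genomes(self, rng):
        seq = _random_seq(rng, 400)
        a = minimizer_sketch(_genome(seq, "a"), SketchParams(k=7, w=4))
        b = minimizer_sketch(_genome(seq, "b"), SketchParams(k=7, w=4))
        assert containment_similarity(a, b) == 1.0

    def test_disjoint_homopolymers(self):
        params = SketchParams(k=5, w=2)
        a = minimizer_sketch(_genome("A" * 100, "a"), params)
        b = minimizer_sketch(_genome("C" * 100, "b"), params)
        assert containment_similarity(a, b) == 0.0

    def test_empty_sketch_conventions(self):
        params = SketchParams(k=15, w=2)
        empty_a = minimizer_sketch(_genome("ACGT", "a"), params)
        empty_a2 = minimizer_sketch(_genome("TTTT", "a"), params)
        empty_b = minimizer_sketch(_genome("ACGT", "b"), params)
        full = minimizer_sketch(_genome("ACGT" * 30, "c"), params)
        assert containment_similarity(empty_a, empty_a2) == 1.0  # both empty, same organism
        assert containment_similarity(empty_a, empty_b) == 0.0
        assert containment_similarity(empty_a, full) == 0.0

    def test_param_mismatch_rejected(self, rng):
        seq = _random_seq(rng, 100)
        a = minimizer_sketch(_genome(seq, "a"), SketchParams(k=7, w=4))
        b = minimizer_sketch(_genome(seq, "b"), SketchParams(k=7, w=5))
        with pytest.raises(SketchError, match="mismatch"):
            containment_similarity(a, b)

    def test_mutated_copy_tracks_kmer_set_oracle(self, rng):
        """Minimizer containment of a 2%-mutated copy stays within 3
        simulation standard deviations of the exhaustive k-mer-set value
        computed on the same pair (replicated over mutation draws)."""
        seq = _random_seq(rng, 10_000)
        params = SketchParams(k=15, w=10)
        base = minimizer_sketch(_genome(seq, "ref"), params)
        observed, expected = [], []
        for rep in range(6):
            mutated = list(seq)
            for pos in np.flatnonzero(rng.random(len(seq)) < 0.02):
                mutated[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            mutated = "".join(mutated)
            sk = minimizer_sketch(_genome(mutated, f"m{rep}"), params)
            observed.append(containment_similarity(base, sk))
            expected.append(oracles.kmer_set_containment(seq, mutated, k=15))
        sigma = np.std(observed, ddof=1)
        for obs, exp in zip(observed, expected):
            assert abs(obs - exp) <= 3 * sigma

    def test_similarity_decreases_with_mutation_rate(self, rng):
        """Expected similarity is non-increasing in the per-site mutation rate."""
        seq = _random_seq(rng, 5_000)
        params = SketchParams()
        base = minimizer_sketch(_genome(seq, "ref"), params)
        means = []
        for rate in [0.0, 0.02, 0.05, 0.10, 0.20]:
            sims = []
            for rep in range(3):
                mutated = list(seq)
                for pos in np.flatnonzero(rng.random(len(seq)) < rate):
                    mutated[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                sk = minimizer_sketch(_genome("".join(mutated), f"m{rep}"), params)
                sims.append(containment_similarity(base, sk))
            means.append(np.mean(sims))
        assert all(means[i] + 0.02 >= means[i + 1] for i in range(len(means) - 1))


class TestPaf:
    def _rec(self, qs, qe, ts=0, te=10, qlen=300, tlen=1000, q="gA", t="gB"):
        return PafRecord(q, qlen, qs, qe, "+", t, tlen, ts, te, qe - qs, qe - qs, 60)

    def test_no_records_is_zero(self):
        assert paf_similarity([], 300, 1000) == 0.0

    def test_full_cover_is_one(self):
        assert paf_similarity([self._rec(0, 300)], 300, 1000) == 1.0

    def test_disjoint_blocks_interval_union(self):
        records = [self._rec(0, 100), self._rec(200, 250)]
        expected = oracles.interval_union_length([(0, 100), (200, 250)]) / 300
        assert paf_similarity(records, 300, 1000) == expected == 0.5

    def test_overlapping_blocks_counted_once(self):
        records = [self._rec(0, 120), self._rec(60, 180)]
        assert paf_similarity(records, 300, 1000) == 180 / 300

    def test_projection_onto_target_when_target_shorter(self):
        rec = self._rec(0, 10, ts=5, te=105, qlen=5000, tlen=200)
        assert paf_similarity([rec], 5000, 200) == 100 / 200

    def test_coordinate_overflow_rejected(self):
        with pytest.raises(Exception, match="exceed"):
            paf_similarity([self._rec(250, 400)], 300, 1000)

    def test_negative_interval_rejected(self):
        with pytest.raises(Exception, match="negative"):
            paf_similarity([self._rec(100, 50)], 300, 1000)

    def test_read_paf_parses_columns(self, tmp_path):
        path = tmp_path / "aln.paf"
        path.write_text("gA\t300\t0\t100\t+\tgB\t1000\t10\t110\t95\t100\t60\tNM:i:5\n")
        (rec,) = read_paf(path)
        assert rec.query_name == "gA" and rec.target_start == 10
        assert rec.residue_matches == 95 and rec.block_length == 100


class TestAllVsAll:
    def test_single_genome(self, rng):
        sk = minimizer_sketch(_genome(_random_seq(rng, 200), "solo"), SketchParams(k=7, w=4))
        m = all_vs_all([sk])
        assert m.ids == ["solo"] and m.values.tolist() == [[1.0]]

    def test_matches_pairwise_containment_and_symmetry(self, rng):
        params = SketchParams(k=7, w=4)
        sketches = [
            minimizer_sketch(_genome(_random_seq(rng, 600), f"g{i}"), params) for i in range(3)
        ]
        m = all_vs_all(sketches)
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else containment_similarity(sketches[i], sketches[j])
                assert m.values[i, j] == pytest.approx(expected)
        np.testing.assert_array_equal(m.values, m.values.T)

    def test_matrix_invariants_and_strand_invariance(self, benchmark_panel):
        m = benchmark_panel["matrix"]
        assert np.all(m.values >= 0) and np.all(m.values <= 1)
        np.testing.assert_array_equal(np.diag(m.values), 1.0)
        np.testing.assert_array_equal(m.values, m.values.T)
        # reverse-complementing one genome leaves its similarities unchanged
        genome = benchmark_panel["genomes"][0]
        flipped = Genome.from_sequence(genome.organism_id, oracles.revcomp(genome.sequence))
        sketches = [minimizer_sketch(flipped)] + benchmark_panel["sketches"][1:]
        m2 = all_vs_all(sketches)
        np.testing.assert_allclose(m2.values, m.values)

    def test_clade_separation(self, benchmark_panel):
        m = benchmark_panel["matrix"]
        clade = benchmark_panel["clades"].organism_clade
        within, between = [], []
        for i, a in enumerate(m.ids):
            for j in range(i + 1, len(m.ids)):
                (within if clade[a] == clade[m.ids[j]] else between).append(m.values[i, j])
        assert min(within) > max(between)

    def test_duplicate_ids_rejected(self, rng):
        params = SketchParams(k=7, w=4)
        sk = minimizer_sketch(_genome(_random_seq(rng, 200), "dup"), params)
        with pytest.raises(SketchError, match="duplicate"):
            all_vs_all([sk, sk])

    def test_paf_backend(self, tmp_path, rng):
        params = SketchParams(k=7, w=4)
        sketches = [
            minimizer_sketch(_genome(_random_seq(rng, length), org), params)
            for org, length in [("gA", 300), ("gB", 1000), ("gC", 500)]
        ]
        paf = tmp_path / "aln.paf"
        paf.write_text(
            "gA\t300\t0\t150\t+\tgB\t1000\t0\t150\t140\t150\t60\n"
            "gC\t500\t0\t100\t+\tgA\t300\t10\t110\t90\t100\t60\n"  # reversed orientation
        )
        m = all_vs_all(sketches, backend="paf", paf_path=paf)
        idx = {org: i for i, org in enumerate(m.ids)}
        assert m.values[idx["gA"], idx["gB"]] == pytest.approx(150 / 300)
        assert m.values[idx["gA"], idx["gC"]] == pytest.approx(100 / 300)
        assert m.values[idx["gB"], idx["gC"]] == 0.0
        np.testing.assert_array_equal(np.diag(m.values), 1.0)

    def test_paf_unknown_id_rejected(self, tmp_path, rng):
        sk = minimizer_sketch(_genome(_random_seq(rng, 200), "gA"), SketchParams(k=7, w=4))
        paf = tmp_path / "aln.paf"
        paf.write_text("gA\t200\t0\t50\t+\tgZ\t900\t0\t50\t50\t50\t60\n")
        with pytest.raises(SketchError, match="gZ"):
            all_vs_all([sk], backend="paf", paf_path=paf)
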