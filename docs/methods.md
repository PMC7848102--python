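# Methods

## Problem and model

`paosvm` frames the recognition of polyphosphate-accumulating organisms
(PAOs) as binary classification over whole-genome similarity. The
working hypothesis is that lineages with confirmed PAO physiology are
genomically closer to one another than to arbitrary microbes, so an
organism's vector of similarities to a fixed reference panel carries
enough signal for a linear separator. The pipeline has four stages —
splicing, sketch-based similarity, feature assembly, soft-margin linear
SVM — each exposed as a library module and a CLI subcommand.

## Splicing

Comparative databases deliver a genome as thousands of segments in no
canonical order. Segments of one organism are concatenated in
lexicographic order of segment id — a declared canonical order so the
result is independent of file ordering — separated by an `N`-run of
length equal to the sketch k (default 15). Since k-mers containing `N`
are never sketched, the spacer guarantees splicing introduces no
chimeric minimizers, and the concatenation order cannot affect the
minimizer *set* beyond the (excluded) junctions. Coordinates are
0-based half-open; segment boundaries are retained on the `Genome`
object. Input normalization maps `U`→`T` and rejects all other IUPAC
ambiguity codes loudly rather than guessing.

## Minimizer sketching and similarity

Sketch parameters: k-mer length `k = 15`, window `w = 10` k-mers,
minimap-like regime; both CLI-configurable. Each window of `w`
consecutive N-free k-mers contributes the k-mer(s) minimizing the hash
of the canonical form (lexicographic min of k-mer and reverse
complement, which makes sketches strand-invariant); ties keep every
tied k-mer. The hash is the splitmix64 finalizer applied to the 2-bit
k-mer code XORed with a fixed seed — invertible, platform-independent,
and deterministic across runs. Sketches are **distinct sets**: a
minimizer occurring many times in a genome counts once. Copy number is
deliberately discarded; the similarity is meant to measure shared
sequence content, not repeat abundance.

Pair similarity is containment normalized by the smaller sketch,
`|A∩B| / min(|A|,|B|)`, chosen over Jaccard because genome lengths in a
mixed panel vary by orders of magnitude and a small genome fully
contained in a large one should score 1. Degenerate cases are pinned:
two empty sketches are similar 1 iff they name the same organism;
empty-vs-nonempty is 0. The matrix is computed once per unordered pair,
mirrored, diagonal forced to 1.

Two estimator properties worth knowing:

* Containment of minimizer sets is a slightly **downward-biased**
  estimate of full k-mer-set containment between diverged genomes
  (~0.03 at 2% per-site divergence, k=15, w=10): a shared k-mer only
  enters the intersection if it is selected as a minimizer in *both*
  genomes, and nearby mutations can displace the window minimum in one
  of them. The test suite checks tracking within 3 simulation standard
  deviations over replicate mutation draws rather than exact agreement.
* Expected similarity is monotone non-increasing in the per-site
  mutation rate (checked over a rate grid with replicates).

A second backend converts PAF overlap records from an external
all-vs-all aligner to the same scale: alignment blocks of each pair are
projected onto the shorter genome, their interval union taken, and the
covered fraction returned, clamped to [0, 1]. How an aligner's overlap
should be normalized is genuinely underdetermined (query, target,
shorter, or total length); normalizing by the shorter genome was chosen
to mirror the containment semantics of the native backend, and is a
documented choice, not an inference about what any particular external
tool intends. The package only parses PAF text it is given; it never
invokes an aligner.

## Features and training sets

The feature vector of organism *i* is row *i* of the similarity matrix
— similarity to all N panel members, in panel order. The dimension is
already the panel size, so no kernel-space mapping or dimensionality
reduction is applied, and values are native [0, 1] so no rescaling. The
self-similarity coordinate (always 1 for panel members) is retained by
default — there is no principled exclusion rule, and dropping it is
exposed via `drop_self` for users who object. Genomes outside the panel
are embedded by computing their containment against each reference
sketch (`embed_new_genome`), which reproduces the matrix row exactly
for panel members.

Negatives are drawn uniformly without replacement from the unlabeled
pool (`sample_negatives`, seeded), matched in count to the positives.
These "negatives" are merely *unconfirmed*: an unknown number are true
PAOs, so the measured accuracy is with respect to noisy labels and the
decision values of "negative"-labeled organisms near the boundary
deserve scrutiny rather than dismissal.

## Linear SVM

The soft-margin primal (penalty `C`, slacks ξᵢ) is solved through its
dual with box constraints `0 ≤ λᵢ ≤ C` and `Σ λᵢ yᵢ = 0`, linear
kernel only — with panel-sized feature dimension there is nothing to
gain from an implicit higher-dimensional map. The solver is SMO-style
maximal-violating-pair coordinate ascent: select i maximizing and j
minimizing `yᵢ − w·xᵢ` over the respective feasible sets, update the
pair analytically, stop when the violation gap falls below `tol`.

* Defaults: `C = 1.0`, `tol = 1e-3`, `max_iter = 10000`. No C is
  prescribed by the problem; 1.0 is the conventional default and the
  benchmark is insensitive to it (the classes are separable). All three
  are CLI flags and serialized with the model.
* Bias: mean of `yᵢ − w·xᵢ` over free support vectors
  (`0 < λᵢ < C`); margin-bound midpoint when none are free.
* Label encoding 0→−1, 1→+1; `sgn(0)` resolved to class 1 so
  prediction is total and deterministic.
* Correctness contract: every fitted model satisfies the KKT conditions
  within tolerance, and on small instances (≤ 12 points) the dual
  objective and predictions are checked in the tests against an
  independent generic QP solution and scikit-learn's SVC. Fitting is
  deterministic; non-convergence raises with the final KKT violation.

## Cross-validation

Stratified partitioning deals each class (after a seeded shuffle)
round-robin into `n_parts` parts, so per-class part sizes differ by at
most one — 1,833 positives over 10 parts gives exactly three parts of
184 and seven of 183; 4,485 unknowns gives five of 449 and five of 448.
The default **nested** scheme then re-deals each part into `n_groups`
stratified groups (18–19 / 44–45 at full scale), trains on nine
seeded-randomly-chosen groups and tests on the held-out group — one
accuracy per part, ten in total; `rotation="full"` averages all ten
hold-outs per part instead. The **parts** scheme is the standard k-fold
rotation (train on nine parts, test on the held-out part). The nested
scheme requires at least `n_groups` members of each class inside every
part (10×10 needs ≥ 100 per class), so the 60-genome synthetic
benchmark uses the parts scheme; both are exposed everywhere.

Reported summary: arithmetic mean and sample standard deviation
(divisor n−1) of the per-part accuracies; the population-divisor
variant is available by flag (`ddof=0`). At 2 printed decimals on ten
fold accuracies the two are indistinguishable, which is why the choice
is documented rather than treated as recoverable. Accuracy
(correct/total) is the reported metric; precision and recall are easy
to derive from the candidate table but are not part of the summary.

Candidate screening scores every organism outside the training
exclusion set with the fitted decision function and sorts descending
(ties broken by id for determinism); `predicted_label` is the sign
convention above.

## Synthetic data generator

`synth` emulates a panel with clade structure correlated to labels via
a two-level star phylogeny: a uniform random root; per-clade ancestors
substituted from the root at `between_clade_divergence` per site;
members substituted from their ancestor at `within_clade_divergence`
(substitutions uniform over the three alternative bases); optional
indels (per-site rate, geometric length with mean 3). A full coalescent
or birth–death simulator would add realism the pipeline cannot see —
only the block structure of the similarity matrix matters — and would
cost the analytic oracles (binomial substitution counts, closed-form
expected k-mer survival) the tests rely on.

Default scenario, which is also the benchmark the acceptance script
runs: 5 clades × 12 genomes × 20 kb, 2% within vs 20% between
divergence, indels off, clade-pure labels on clades 0–1 (24 positives,
36 unlabeled). At these settings within-clade containment (~0.5) and
between-clade containment (~0.003) are separated by two orders of
magnitude, so the benchmark demonstrates *pipeline correctness*
(plumbing, stratification, solver, ranking) — it does not demonstrate
that real PAO/non-PAO genomes are this separable. Real panels add
shared core genes across clades, horizontal transfer, repeats and
wildly varying genome sizes, all of which compress the similarity gap;
passing the benchmark therefore bounds software error, not biological
error. Indels are off in the benchmark because they perturb minimizer
windows and are exercised separately in robustness tests. Problem sizes
throughout the suite (20 kb genomes, 60-organism panels, ≤ 12-point QP
cross-checks) were chosen so every oracle remains exhaustive and
analytic at full strength.

## Numerical and degenerate-input choices

* Genomes shorter than k (or with no run of w valid k-mers) sketch to
  the empty set — not an error; their similarities follow the empty-set
  conventions above.
* Matrix I/O round-trips at 6 decimal places; validation enforces
  squareness, header/index agreement, symmetry, unit diagonal, [0, 1]
  range.
* SMO uses a single working-set cache (the precomputed kernel matrix);
  no shrinking heuristics — correctness is guarded by the QP-oracle
  equivalence tests, and panel sizes in scope do not need them.
* All randomness (simulation, sampling, shuffling, group choice) flows
  through explicitly seeded NumPy generators; derived seeds stay below
  2³¹. Identical config + inputs ⇒ byte-identical outputs (manifests
  record config and input hashes).

## Known limitations

* Balanced negatives are unlabeled organisms, not verified non-PAOs;
  accuracy is measured against noisy labels.
* Containment similarity ignores copy number and, via min-
  normalization, can rate a plasmid-sized sequence maximally similar to
  any genome containing it.
* The nested CV scheme's group-level split trains each fold on ~9% of
  the panel; its accuracies are noisier than standard k-fold, which is
  why both schemes are exposed.
* No hyperparameter search, probability calibration, non-linear
  kernels, or multiclass support; no aligner invocation or database
  download.
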