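# paosvm

Screen microbial genomes for candidate **polyphosphate-accumulating
organisms (PAOs)** — the microbes that drive enhanced biological
phosphorus removal in wastewater treatment — directly from genome
sequence, without wet-lab assays.

Identifying PAOs experimentally (anaerobic/aerobic cycling, phosphate
release/uptake assays) is slow and costly, while thousands of sequenced
genomes sit in comparative databases unannotated for phosphorus
metabolism. `paosvm` treats PAO identification as a supervised binary
classification problem over whole-genome similarity:

1. **Splice** each organism's genome segments into one long-chain
   sequence (segments joined in lexicographic id order with an `N`
   spacer of length k, so no chimeric k-mer spans a join).
2. **Sketch** every genome by its canonical *(w, k)*-minimizers: within
   each window of `w` consecutive N-free k-mers, keep the k-mer whose
   hashed canonical form (lexicographic min of the k-mer and its reverse
   complement) is minimal. Defaults `k = 15`, `w = 10`.
3. **Compare** all genomes pairwise by minimizer containment,

   `sim(A, B) = |M_A ∩ M_B| / min(|M_A|, |M_B|)  ∈ [0, 1]`,

   giving a symmetric N×N similarity matrix with unit diagonal.
   Alternatively, overlap records from an external all-vs-all aligner
   (PAF, e.g. minimap2) are converted to the same scale as the covered
   fraction of the shorter genome of each pair.
4. **Classify** with a soft-margin linear SVM. Each organism's feature
   vector **x** is its similarity-to-panel row; with labels
   y ∈ {−1, +1} (1 = known PAO), the classifier solves

   `min ½‖w‖² + C Σᵢ ξᵢ  s.t.  yᵢ(w·xᵢ + b) ≥ 1 − ξᵢ,  ξᵢ ≥ 0`

   via its Lagrangian dual (`0 ≤ λᵢ ≤ C`, `Σ λᵢ yᵢ = 0`, linear kernel
   `K(xᵢ, xⱼ) = xᵢ·xⱼ`) with an SMO-style maximal-violating-pair solver.
   Predictions are `sgn(Σ λᵢ yᵢ K(xᵢ, x) + b)`.
5. **Evaluate** with doubly stratified 10-fold cross-validation
   (class-stratified parts, each split into stratified groups, train on
   nine groups / test on one), and **rank** unlabeled organisms by
   decision value to propose candidate PAOs.

Because the negative class is "not *confirmed* a PAO", negatives are a
balanced uniform sample of the unlabeled pool taken at face value — a
known label-noise caveat discussed in `docs/methods.md`.

## Worked example

Everything below is reproducible from the built-in clade-structured
simulator; no external data needed.

```sh
paosvm simulate --out-dir run --n-clades 5 --genomes-per-clade 12 \
    --genome-length 20000 --within 0.02 --between 0.20 --seed-simulation 2021
paosvm similarity --fasta run/genomes.fasta --out run/matrix.tsv
paosvm cv --matrix run/matrix.tsv --labels run/labels.tsv \
    --out run/cv.tsv --scheme parts --seed-partition 3
```

which prints

```
mean accuracy 1.0000 +/- 0.0000
```

The 60 simulated genomes fall into 5 clades (2% within- vs 20%
between-clade divergence); the two positive clades are labeled PAO. At
these divergences every within-clade similarity (≥ ~0.47) exceeds every
between-clade similarity (≤ ~0.01), the feature rows are block
structured, and the linear SVM separates the classes perfectly in every
fold — the synthetic stand-in for the high cross-validated accuracy the
method attains on a real comparative-genomics panel. Train a final
model and rank a held-out pool:

```sh
paosvm train --matrix run/matrix.tsv --labels run/labels.tsv \
    --out run/model.json --n-negatives 18 --seed-negatives 13
paosvm predict --matrix run/matrix.tsv --model run/model.json \
    --exclude run/model.json.training_ids.tsv --out run/candidates.tsv
```

```
scored 18 organisms; 0 predicted positive
```

`run/candidates.tsv` lists each held-out organism with its decision
value, most PAO-like first (here all held-out organisms come from
negative clades and all score below 0). Every command writes a
`*.manifest.json` (config echo + input SHA-256) so identical configs
give byte-identical outputs.

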