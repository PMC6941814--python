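# Methods

`motifcnn` studies how convolutional network architecture — specifically
max-pool geometry and filter size — determines whether sequence motifs are
learned as *localist* representations (whole motifs inside single
first-layer filters) or *distributed* representations (partial motifs
assembled hierarchically in deeper layers). Everything runs on synthetic
sequences with known ground truth, so the quality of learned
representations can be quantified exactly.

## The synthetic benchmark

Each example is a 200-nt DNA sequence whose background bases are i.i.d.
uniform over {A, C, G, T}. A count k ~ Uniform{1..5} of binding sites is
drawn with replacement from a pool of 24 strand-motifs (12 transcription
factors × forward/reverse-complement). A site is *realised* by sampling
each position independently from the motif's probability column, then
written over the background at a uniformly chosen position subject to a
buffer of at least one background nucleotide between sites and from both
sequence ends (rejection sampling over joint placements, 1,000 attempts
before re-drawing). The 12-bit label marks which TFs are present on either
strand. Background subsequences that happen to resemble a motif are *not*
labelled; the labels therefore carry a small false-negative rate exactly
as a peak-called dataset would. Defaults: 25,000 sequences split
0.7/0.1/0.2 into train/validation/test by a seeded permutation.
Coordinates are 0-based half-open everywhere; tensors are one-hot
(4 × L, rows A, C, G, T).

### The motif fixtures

The 12 ground-truth matrices bundled in
`motifcnn/data/synthetic_tf_motifs.meme` are **synthetic stand-ins** for
the JASPAR matrices of Arid3, CEBPB, FOSL1, Gabpa, MEF2A, MAFK, MAX, NFYB,
SP1, SRF, STAT1 and YY1: the exact versioned JASPAR matrices are not
redistributable inside this package, so each stand-in keeps the factor's
approximate catalogue width (6–16 columns), its literature consensus core
(e.g. the MAX E-box CACGTG, the SRF CArG box CC(A/T)₆GG, the SP1 GC-box)
and a realistic information content (8–18 bits total), with consensus-base
probabilities of 0.86–0.97 in core columns and degenerate flanks. The
study's conclusions are architecture contrasts, not motif-identity claims,
and are insensitive to the precise matrices. JASPAR count matrices can be
substituted at any time via `load_motifs(path, format="jaspar_pfm")`
(counts are column-normalised with no pseudocount — sites are sampled from
the matrix, never log-odds scored, so a zero-probability base simply never
occurs).

What the generator deliberately does **not** model: genomic GC bias,
repeats, dinucleotide structure, cooperative/overlapping sites, or
position-dependent site placement. Passing tests therefore demonstrate
the architecture effects under idealised conditions, not performance on
real ChIP-seq data.

## Model family

Every variant shares one skeleton:

    conv(30 filters × 19 nt) → BN → ReLU → maxpool(p₁) → dropout 0.1
    conv(128 × 5)            → BN → ReLU → maxpool(p₂) → dropout 0.5*
    dense(512) → ReLU → dropout 0.5 → dense(12) → sigmoid

(*conv-block dropout is 0.1; the 0.5 applies to the dense block.)
Convolutions are stride-1 cross-correlations with "same" zero padding.
Pooling windows equal their strides unless stated; output length is
⌈L/stride⌉ with minimal right zero-padding (zeros never beat a ReLU
activation because argmax ties break leftmost). In the coupled series
p₁·p₂ = 100 — CNN-1 (1,100), CNN-2 (2,50), CNN-4 (4,25), CNN-10 (10,10),
CNN-25 (25,4), CNN-50 (50,2), CNN-100 (100,1) — so every member feeds an
identical 256-unit flattened input to the dense layer and has an identical
parameter count; only the position of the spatial information bottleneck
moves. Controls: CNN_9-* and CNN_3-* shrink the first-layer filters to
9/3 nt; CNN-50-2 pools with window 50 but stride 2 (large spatial
uncertainty, overlapping receptive fields); CNN_19-1-2 shrinks the
second-layer filters to size 1; CNN-1-1-100 inserts a third conv layer
(128 × 5) and defers all pooling (size 100) until after it.

Training: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) at a constant learning rate on
mini-batches of 100, binary cross-entropy summed over the 12 classes and
averaged over the batch, L2 of 1e-6 on weight matrices only (not biases or
BN parameters), He-normal initialisation everywhere, and *early stopping
by checkpoint selection*: the run always lasts the configured number of
epochs and the parameters with the lowest validation loss are restored.
Batch-norm uses ε 1e-5 and running-statistic momentum 0.9 (library
defaults; nothing downstream is sensitive to them).

The layer stack, backpropagation and Adam are implemented in-package on
numpy (im2col convolutions through BLAS; a fused batch-norm+ReLU pair in
numba for the dominant elementwise cost). Correctness is enforced by
float64 finite-difference gradient checks over the full stack and by an
exact equivalence test between the fused kernel and the plain layer
composition.

## Filter interpretation

A first-layer filter is rendered interpretable by alignment: scan it over
every test sequence (activations taken after batch-norm and ReLU, before
pooling), record each sequence's maximum activation and its position
(leftmost on ties), discard sequences below 70% of the filter's maximum
achievable activation, and extract the filter-sized window under each
surviving maximum (windows overrunning a sequence end are dropped). Column
base counts of the aligned windows, normalised, give the filter's position
probability matrix (PPM); per-position information content
IC_i = 2 + Σ_n p_i(n)·log₂ p_i(n) scales logo letters. Two readings of
"maximum achievable activation" are provided: the default **empirical**
ceiling (the largest activation observed across the scanned set — robust,
and the convention used throughout) and an **analytic** ceiling for layer
1 (fold the batch-norm affine into the convolution using running
statistics, then sum each position's best base weight). A filter whose
threshold removes every sequence yields an empty-flagged PPM that stays in
all denominators but is excluded from matching and export.

Deeper layers are scanned the same way *only* when no pooling precedes
them (CNN-1's second layer; CNN-1-1-100's second and third): pooling
destroys the positional correspondence the alignment needs, and the
scanner refuses such layers. Feature-map positions map to input windows of
the receptive-field width (19 + Σ(k_i − 1): 23 nt for layer 2, 27 nt for
layer 3).

## Motif matching

Filter PPMs are compared against the ground-truth pool with a
Tomtom-style statistic: slide the query over each target (both strands),
score every offset with ≥ 4 overlapping columns by the sum of column-wise
Pearson correlations (zero-variance columns contribute 0), and take the
best alignment over the whole database. Significance is a permutation
test: 1,000 seeded column-shuffles of the query are each given the same
best-over-everything search, and the p-value (1 + #better)/(1 + 1,000) is
scaled by the number of database motifs (12) to mimic an E-value; a filter
matches when E ≤ 0.1. Pooling the null over the entire search keeps the
decoy false-positive rate near 1% at that cutoff while exact and noisy
motif copies still match (both properties are asserted in the tests).
Ties between targets break by score, then name. This statistic is a
documented stand-in for MEME-suite Tomtom, whose exact p-value dynamic
program is not reimplemented; an optional subprocess wrapper
(`motifcnn.match.run_tomtom`) uses the real binary when present and
degrades to a logged no-op otherwise. The headline quantity is the
*relevant match fraction*: matched filters over **all** filters of the
layer, empties included.

## Desk-scale profile and what it can show

The full protocol (25,000 sequences × 100 epochs × 5 trials × 16
variants, constant learning rate 3e-4) is hours-to-days of CPU. The
package therefore defines a desk-scale profile used by the test suite and
`scripts/acceptance.py`: one shared dataset, one trial per variant, and a
shortened schedule whose constant learning rate is raised so the total
optimisation displacement stays comparable (Adam's step size is invariant
to loss scale, so schedule length and learning rate trade off directly).
Empirically, class discovery — a filter locking onto one motif — is the
slow, stochastic phase: classes are discovered sequentially, discovered
classes reach per-class AU-ROC ≈ 0.95–0.99 quickly, and a run's mean
AU-ROC is governed by how many of the 12 classes its budget discovered.
Raising the rate much beyond ~2.5e-3 trades discovery for noise and
plateaus lower.

Consequences, stated plainly:

* classification metrics at desk scale sit below the
  full-protocol values by roughly the share of undiscovered classes;
* the *localist* match fractions (CNN-25-type architectures) are robust —
  filters of discovered classes carry whole motifs early;
* the near-zero match fractions of *distributed* architectures (CNN-2,
  CNN-1 layer 1) are an asymptotic property: at intermediate convergence
  their first-layer filters still hold transient whole-motif information
  and the alignment windows (cut from real embedded sites) can resemble
  full motifs. Desk-scale runs therefore overestimate those fractions;
  only the direction of the contrast, not its full-protocol magnitude, should
  be expected from short budgets.

The desk calibration was chosen on CNN-25 validation loss alone (never on
the benchmark's reported values): schedules of at least half the full
protocol's ~17,500 steps pair best with a constant rate of 1e-3, shorter
schedules with 2.5e-3, and rates beyond ~2.5e-3 or at the full protocol's
3e-4 both lose — the former to gradient noise, the latter to an
undershot displacement budget.

`scripts/acceptance.py` fixes the desk-scale study at one shared
25,000-sequence dataset (the benchmark's own size) and these per-variant
schedules, sized so the whole session is roughly a quarter hour of
single-CPU training with compute weighted toward the variants whose
quantities are meaningful at desk scale:

| variant      | epochs | rate   | variant       | epochs | rate   |
|--------------|-------:|--------|---------------|-------:|--------|
| CNN-25       |     70 | 1e-3   | CNN-2         |      6 | 2.5e-3 |
| CNN_9-25     |     50 | 1e-3   | CNN-50-2      |      4 | 2.5e-3 |
| CNN_3-50     |     16 | 2.5e-3 | CNN-1         |      6 | 2.5e-3 |
| CNN-25 (120) |     12 | 2.5e-3 | CNN-1-1-100   |      2 | 2.5e-3 |

The scaled-replication tier of the test suite uses the same calibration
on a 10,000-sequence dataset (CNN-25 150 epochs at 1e-3; CNN-2 80,
CNN_3-50 30 and CNN_3-2 60 epochs at 2.5e-3).

## Numerical and design choices

* Probability columns must sum to 1 within 1e-6; motif files are validated
  on load and parse errors name the offending motif and column.
* The motif-count distribution over {1..5} is uniform over the stated
  range.
* Dropout is applied after pooling (after each conv block), the standard
  placement.
* AU-ROC/AU-PR use scikit-learn (midrank tie handling); a class without
  both label values in a split is reported NaN with a warning and excluded
  from means.
* Sweeps share one dataset per data seed across variants; trial seeds vary
  only initialisation, shuffling and dropout.
* Training is bitwise reproducible for a fixed seed on a fixed
  single-threaded BLAS backend.

## Known limitations

* The matcher is not Tomtom; absolute E-values differ even though the
  match/no-match contrasts agree on clean queries (calibration tests pin
  sensitivity 1.0 and decoy FPR ≤ 5%).
* Single-trial desk runs inherit the full stochasticity of class
  discovery; full-protocol values are 5-trial means.
* An in-vivo arm (DeepSEA-derived ChIP-seq data, 1,000-nt
  inputs) is out of scope; `input_length` is a free parameter but nothing
  here has been validated against ENCODE data.
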