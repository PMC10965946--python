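# Methods

## The predictor

`psphunter` frames phase-separation prediction as binary classification of
proteins from 122 features in eight named blocks (see README for the
layout). The classifier is a scikit-learn random forest with 500 trees
(`n_estimators=500`, other hyperparameters at library defaults, fixed
`random_state`). Multimodal inputs are integrated directly — one forest on
the concatenated blocks — rather than by stacking or probability averaging;
forests tolerate heterogeneous scales, so no feature standardization is
applied.

Datasets are assembled balanced: for each repeat an equal number of
negatives is drawn without replacement from the background pool, and
positives and negatives are split 70/30 into train and held-out test
separately so both partitions stay balanced. Per-repeat seeds derive from
the master seed by unit increments. Before sampling, a greedy redundancy
filter drops any sequence whose 5-mer Jaccard similarity to an already-kept
sequence exceeds 0.5 — a fast proxy for clustering at roughly 30% pairwise
identity (5-mer Jaccard falls off steeply below ~40% identity, so 0.5 is a
conservative cut); an adapter point accepts externally computed cluster
representatives instead. The filter runs on the full sets before splitting,
so train/test leakage through near-duplicates is excluded across repeats as
well.

After an initial fit, features are ranked by impurity importance and the
model is retrained on the top 60 columns (ties broken toward the lower
column index so selection is deterministic); 60 was retained as the default
because performance plateaus there on the reference data this design
follows. Evaluation reports AUC from the ranked scores plus recall,
precision, F1, accuracy and MCC from the confusion matrix at probability
threshold 0.5. Zero-denominator cases (no predicted positives, one-class
MCC) are reported as 0 rather than NaN. Proteome screening uses a score
cutoff of 0.82, the high-specificity operating point; it is a parameter,
not a constant.

## Feature conventions

* **Profiles.** PSSM and HMM matrices are compressed identically: each row
  is z-scored across its 20 entries with the population standard deviation
  (ddof=0); zero-variance rows map to zero rows instead of NaN; column
  means over all rows are summed within the four residue categories. The
  PSI-BLAST parser takes the log-odds payload (first 20 columns). HH-suite
  emissions are decoded from the stored integers as 2^(−x/1000), `*` → 0.
* **Quantiles.** The conservation five-number summary uses
  linear-interpolation quantiles (numpy default), so the block is exactly
  reproducible.
* **Nonstandard residues.** Default policy maps B→D, Z→E, J→L, U→C, O→K;
  X is kept, counts toward length, but is excluded from category counts,
  doublets and 3-grams. A `strict` mode rejects such records, a `drop`
  mode skips them. The mapping slightly distorts composition for
  ambiguity-heavy entries; that is the accepted cost of keeping them.
* **Missing blocks.** An unavailable input (no profile, no tracks, no PPI
  node) yields a zero-filled block with its availability mask recorded.
  Models must be trained and applied under the same mask policy; the mask
  is stored with the extractor inputs, and the feature-count check at
  prediction time catches gross mismatches.
* **Abundance** enters as log10(ppm + 1); any monotone transform is
  equivalent for a forest, the log keeps the column readable.
* **Betweenness** is unnormalized (raw shortest-path counts) on the full
  graph; the convention is recorded here so trained models are applied to
  identically computed features.
* The variant slot triple (total/pathogenic/neutral) completes the
  11-dimensional annotation block; the exact composition of that block is
  a reconstruction and is flagged as such.

## Sequence embedding

Proteins are read as three sentences of nonoverlapping 3-grams (offsets 0,
1, 2 — together covering all L−2 consecutive 3-grams). A CBOW word2vec
model with negative sampling is trained on this corpus: dimension 60,
window 70, 5 negatives, learning rate 0.025 decaying linearly to 1e-4,
unigram^(3/4) noise distribution, vocabulary from all corpus words
(min_count 1). The trainer is a compact single-threaded numpy
implementation; training order is fixed corpus order, so results are
bitwise reproducible for a given seed. Three epochs are the package-level
working default for the synthetic cohorts (the corpus is small and the
forest only needs stable relative geometry); five is the constructor
default. A protein's embedding is the unweighted mean of its in-vocabulary
3-gram vectors (sum pooling available); all-out-of-vocabulary sequences
map to the zero vector with a warning. The embedding corpus is a
configuration input — by default the training sequences themselves.

## Truncation scan

For a protein of length L and unit u = 20 (about 1/30 of a typical
phase-separating protein; configurable), the window for center i is
[i − u/2, i + u/2 − 1] (1-based inclusive; the even window sits
asymmetrically by this fixed convention) and admissible centers are
⌊u/2⌋+1 … L−⌈u/2⌉, leaving exactly 10 undefined positions at each terminus
for the default unit. Each variant's sequence-derived blocks (composition,
word2vec; plus profile/conservation/funcsite blocks when their per-residue
inputs are present, sliced to the retained positions) are recomputed;
annotation and network blocks are frozen at wild-type values, because an
in-silico edit cannot change curated protein-level annotations. The
per-residue score is δ_i = mean variant score − variant-i score. The mean
of variants is the default reference — it centers the track so that
ordinary windows sit near zero — and the full-protein score is recorded on
the track and switchable as the alternative reference; on the synthetic
cohorts both rank key windows identically.

Candidate key residues are the top-N positions by δ with N =
round(p·L), p banded by length: 5% (L ≤ 500), 4% (500 < L ≤ 1000), 2%
(1000 < L ≤ 2000), 1% (L > 2000). Rounding is half-up; boundary lengths
fall in the lower-percentage band by the stated inequalities; ties in δ
break toward the smaller position; N = 0 after rounding keeps one
candidate with a warning. An absolute-count mode (e.g. the 20–40-residue
heuristic, one to two truncation units) is available via `n_candidates`.
Maximal runs of consecutive candidates (gap tolerance 0, configurable)
form key regions, ranked by mean δ.

Mutation impact is score(wild type) − score(mutant) with the same
recompute/freeze rules; substitutions verify the stated reference residue
against the sequence and fail loudly on mismatch. Fusion constructs append
a tag to the C terminus; appended residues have no per-residue side data,
so track-derived fractions for fusions are computed over the covered
wild-type positions only, while the length feature reports the fused
length.

## Synthetic cohorts

The generator plants a recoverable, localized signal rather than imitating
real LLPS biophysics. Positives differ from background-frequency negatives
by: G/P composition weighted ×1.5; a 40-residue block of sticky aromatic
3-grams (aromatic–G/S–aromatic, drawn from a shared 8-word vocabulary)
alternating with G/P spacer pairs, planted ≥ 30 residues from either
terminus and marked disordered in the residue tracks; PTM annotation
density ×2; abundance ×2; denser PPI connectivity (edge probability 0.08
within positives vs 0.02 background). Secondary-structure and disorder
track baselines differ only mildly between classes. The effect sizes are
deliberately balanced so that the planted block — not the global
protein-level contrasts — carries a substantial share of the
discriminative signal; if the global contrasts dominate, the forest's
probabilities saturate near 1 for positives and the truncation scan loses
contrast. Sequence length is uniform on 150–800 by default (150–450/500 in
the test and acceptance cohorts, which keeps scans fast without changing
any mechanism).

What the generator does **not** emulate: real profile content (PSSM/HMM
blocks are exercised on hand-built files, not fixture cohorts),
phylogenetic correlation between sequences, realistic disorder/PTM
co-occurrence structure, multi-block or discontinuous LLPS regions, and
the long-tailed length distribution of real proteomes. Passing the
planted-signal tests therefore demonstrates that the machinery recovers a
learnable, localized signal end to end — not that the model generalizes
to real proteomes, which requires real training data and profiles.

## Problem sizes and determinism

The test and acceptance cohorts use 40–50 positives and negatives, 3
embedding epochs, and scans over 12–15 positives; the forest keeps its
500-tree default in the acceptance run and uses 300 trees in the shared
test fixture. All randomness flows from explicit
`numpy.random.default_rng` seeds (per-repeat and per-stage seeds derived
by fixed increments), forests are single-threaded, and the embedding
trainer is single-threaded, so every reported number is reproducible
bit-for-bit from the seed.

## Known limitations

* The word2vec trainer is minimal (no subsampling, no hierarchical
  softmax, no vocabulary pruning); it is adequate for 3-gram corpora of
  thousands of words, not for corpora orders of magnitude larger where
  training throughput dominates.
* The 5-mer Jaccard redundancy filter is a heuristic stand-in for
  identity-based clustering; borderline (~30% identity) pairs can be kept
  or dropped differently than blastclust would.
* Feature count is 122; model metadata records the realized count rather
  than assuming any nominal total.
* Scan cost is one forest evaluation per residue; for very long proteins
  (L > 5000) expect minutes per protein at 500 trees.
* The fusion-construct convention (frozen annotations, track fractions
  over covered positions) is one defensible choice among several; it is
  recorded here and in the extractor docstring.
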