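# Methods

## Scanning model

A motif is a position probability matrix (PPM) over the 20 amino acids with an
attached 0th-order background. Scoring follows the FIMO convention: the window
score is the log₂ likelihood ratio of the window under the motif versus the
background, summed per position, with a pseudocount added as a fraction of the
background frequency:

    s(i, a) = log₂( (p[i,a] + α·b[a]) / ((1+α)·b[a]) ),   α = 0.01 by default.

Unknown residues (`X`) contribute exactly 0 bits at any position and windows
consisting solely of `X` are assigned p = 1 (they carry no evidence). Protein
scanning only; there is no reverse strand.

**Exact p-values.** The null distribution of window scores under an i.i.d.
background is computed by positionwise convolution on an integer score lattice
(the standard PWM p-value DP). Scores are discretized to 1/1000-bit bins by
default (configurable; at least 100 bins/bit enforced); each position
contributes a 20-spike distribution and the convolution is carried out by
shifted adds, so the result is exact up to discretization — no FFT error.
P-values are read from the conservative (upper) side of the query score's bin,
and scanning uses the same integer matrix as the DP so hit p-values are
internally consistent. With a zero pseudocount a zero-probability cell has a
−∞ log-odds entry; for the DP such cells are clamped 20 bits below the finite
minimum, which leaves every achievable tail unchanged.

**FDR.** q-values are Benjamini–Hochberg, computed per motif across *all*
scanned windows of the input set; ties in p are broken by sequence order then
start position so the ranking is reproducible. Hits are kept at q ≤ 10⁻⁴, the
stringent cutoff used to build the curated motif set. A per-motif (rather than
pooled) correction is a deliberate choice: it makes each motif's hit list
independent of which other motifs were scanned.

Coordinates are 1-based inclusive everywhere. When an input set is truncated
(e.g. removal of the first 50 residues to discard the conserved DNA-binding
domain), the truncation offset is retained so reported positions can be mapped
back to full-protein numbering.

## Curated fixtures

The package ships the ten reference TFRs, their 37 curated CTD motifs
(consensus, matched occurrence, positions, q-value, subfamily) and the eleven
proposed PROSITE signatures with their published expected-random-match counts.
Two reconstruction caveats, both flagged in the data files:

* The original motif PPMs are not redistributable, so
  `curated_motif_matrices()` rebuilds synthetic sharp matrices from each
  consensus/matched pair (mass ~0.95 on the consensus letter when it equals the
  matched letter, split between the two otherwise, ambiguity codes spread over
  their residue pair, 5% flat floor). These reproduce the annotated occurrence
  positions under scanning, which is the property the pipeline exercises; they
  are not the discovery-time matrices.
* The reference protein sequences themselves are likewise not shipped;
  `synthetic_carrier_sequences()` builds stand-ins that embed every curated
  matched sequence at its printed position over a random background
  (overlapping annotations are cross-checked for consistency during
  construction). One curated row (tFadR-2) prints a 14-position span for a
  15-residue occurrence; it is transcribed as printed and flagged, and the
  carrier plants the full 15-mer from its start position.

## Selection protocol

Classes are balanced by downsampling to 300 sequences per subfamily (smaller
classes are kept whole, mirroring the one 104-member subfamily in the intended
corpus). The feature table holds each sequence's best hit score per motif,
zero-imputed; columns are centered and scaled with the sample (n−1) standard
deviation, statistics estimated on the training partition only. A stratified
3:1 train/test split feeds 3-repeat, 3-fold cross-validation of six model
families: decision tree, random forest, elastic-net multinomial logistic
regression, k-nearest neighbours, PLS-DA (PLS regression on one-hot classes,
argmax decode, component count auto-set to the admissible maximum) and a
single-hidden-layer perceptron. A model survives if its best resample reaches
60% global accuracy; fewer than two survivors is an error because a
cross-model consensus is then undefined.

**Importance.** Native importances of different model families are not
comparable, so a single model-agnostic measure is used for all of them:
per-class permutation importance on the training split — the drop in that
class's recall when one predictor's column is permuted, averaged over three
permutations. Absolute importances are max-normalized to 100 within each
model; a motif is selected for a subfamily when its scaled importance reaches
the cutoff (default 50/100) in *every* surviving model, and selected motifs
are ranked by mean scaled importance.

A structural consequence, visible in the tests: when k classes are separable
on k decisive features, any k−1 of them suffice, so a tree or knn model may
legitimately assign zero permutation importance to one class's motif and the
all-models intersection stays empty for that class. The corpus-shaped
benchmark below quantifies how often this costs a recovery.

## Conservation and patterns

Motif hits of equal width stack into an ungapped alignment, replacing a full
multiple sequence alignment for the motif window. Columns get frequencies
(optionally with a pseudocount; X never counts), Shannon entropy, information
content IC = log₂20 − H ∈ [0, 4.32] bits, logo heights freq·IC, and a 1–9
grade from 9-quantile binning of IC across the stack's columns (9 = most
conserved). The grades are a deliberately simple surrogate for phylogeny-aware
conservation scores: they order columns within one motif but are not
comparable to Bayesian rate estimates. Entropy is the plug-in estimate by
default (stacks in intended use have hundreds of rows); a Miller–Madow
correction is available as a flag. Logo profiles default to pseudocount 0
(percentage shares); pattern derivation defaults to 0.5.

Pattern derivation per column: fixed residue at top frequency ≥ 0.98,
otherwise the smallest descending-frequency set (≤ 4 residues) with combined
frequency ≥ 0.95, otherwise a wildcard; consecutive wildcards merge into
`x(n)`. The thresholds formalize what was manual logo/alignment curation in
the original workflow and are configurable. ERM multiplies per-element
residue-class probabilities under a Swiss-Prot composition table (shipped with
provenance; swappable) and scales by 50,000,000 residues, ignoring edge
effects. A pattern is recommended as a signature when ERM ≤ 10⁻², or when
ERM ≤ 0.1 and a reference search hits only homologs of the source protein.

## Similarity diagnostics

Pairwise identity is 100 × identical columns / alignment length from a global
BLOSUM62 alignment with gap open −10 and extension −0.5 (Biopython
PairwiseAligner). This is one defensible convention among several (identity
over shortest sequence, over matched columns, etc.); it is declared in the
distribution's provenance. Distribution comparisons report the 1-D Wasserstein
distance, two-sample KS and Cramér–von Mises statistics with p-values
(asymptotic for large samples, exact for tiny ones via scipy), and the
rank-biserial effect size r = 1 − 2U/(n₁n₂). Redundancy reduction uses
deterministic longest-first greedy clustering by representative identity — it
preserves the construct (declustering at 90/75/50%) without CD-HIT's word
filters. The stability control draws 30 random subsets of 300 per clustering
level and summarizes all between-draw distances by median and maximum.

## Synthetic benchmarks

The generator plants motif occurrences sampled from per-column PWMs
(probability c on the consensus letter, the rest spread proportionally to the
background) at uniform non-overlapping positions in i.i.d. background
sequences; placement uses rejection sampling with 100 retries and fails loudly
rather than allowing overlaps, so the truth table is unambiguous. The
`paper-small` preset reproduces the corpus shape the selection protocol targets
— 14 subfamilies, 300 sequences each with one of 104 (4004 total), lengths
150–250 (ligand-binding-domain scale after N-terminal truncation), one
exclusive motif per subfamily at conservation 0.9 with widths cycling 8–15,
plus two family-wide shared motifs that selection must down-rank. A `tiny`
preset (3 × 40) exists for smoke tests.

What the synthetic benchmarks do show: exact p-value correctness, ≥95% recall
of planted occurrences at conservation 0.95, and recovery of ≥80% of planted
exclusive motifs as their subfamily's top-ranked consensus pick across five
seeds, with shared motifs never selected. What they do not show: behaviour
under phylogenetic correlation between sequences, indels inside motifs,
composition bias, or class-dependent sequence length — real corpora have all
four, and the uniform background makes every planted motif unusually easy to
tell from its context.

## Numerical and implementation choices

* Score lattice 1/1000 bit; conservative bin-edge p-values; BH ties broken
  positionally.
* Background floors at 10⁻⁶ per residue, then renormalizes.
* Feature scaling uses the sample (n−1) standard deviation; constant columns
  become all-zero and are flagged rather than dropped.
* All randomness flows through explicit seeds (`numpy.random.default_rng`);
  model fitting derives independent child seeds from one master seed, so a fit
  is reproducible end to end and invariant to row/column order of the feature
  table (rows and columns are canonically sorted before fitting).
* CLI outputs embed a digest of the generating configuration; reruns with the
  same configuration are byte-identical.

## Known limitations

* Scan q-values depend on the scanned window universe; they are not comparable
  to q-values computed against a different corpus (in particular the published
  per-motif q-values, which were computed on the full superfamily).
* The ERM figures inherit the uncertainty of the composition-table vintage;
  factor-level agreement is the realistic expectation.
* Conservation grades and the greedy clustering are documented surrogates, not
  reimplementations, of ConSurf and CD-HIT respectively.
* PROSITE anchors (`<`, `>`) and excluded sets (`{..}`) parse and match but are
  never produced by derivation.
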