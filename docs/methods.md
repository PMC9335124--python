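# Methods

This note documents the models and procedures implemented in `pepbinder`,
the parameter choices that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Enrichment calling from selection counts

Reads from each sequenced sample (naive library R0, round-1 pool R1,
round-2 target arm, and bead-only / unrelated-antibody round-2 controls)
are reduced to per-sample peptide counts and normalized to
parts-per-million of the sample's total accepted reads, so calls are
invariant to sequencing depth. For each peptide and each control arm we
compute

- the abundance ratio `R = mean ppm(target) / max(mean ppm(control), pseudo)`,
  with a pseudo-abundance floor (default 1 ppm) because true binders are
  frequently absent from controls and a zero denominator is otherwise
  undefined;
- a one-tailed Welch t-test of mean(target) > mean(control) across
  replicates on the raw ppm scale (no log transform, no multiple-testing
  correction — the operating criterion is the raw `p <= 0.05`).

A peptide is a hit only if `R >= 2` and `p <= 0.05` hold against **every**
control arm (`control_mode="each"`, the default); pooling all control
replicates into one comparison group is available as
`control_mode="pooled"`. The Welch statistic is evaluated directly (with
the Welch–Satterthwaite degrees of freedom) rather than through
`scipy.stats.ttest_ind` so that the zero-variance limit is well defined:
identical groups give (t = 0, p = 0.5), and a zero-variance difference in
means gives p = 0 or 1.

Hit clustering embeds each residue as its 20-entry BLOSUM62 substitution
row (so an L-mer is a 20·L vector) and applies average-linkage
agglomerative clustering on Euclidean distance, cut at a configurable
number of clusters (5 by default). This is a pragmatic reconstruction of
profile-similarity grouping; no claim of a canonical procedure is made.

## Dataset preparation

Redundancy removal follows the CD-HIT convention: identity is matching
positions over the ungapped alignment for equal lengths, or
global-alignment matches divided by the shorter length otherwise; greedy
incremental clustering visits candidates longest-first (lexicographic
tie-break) and keeps cluster representatives, returned in input order.
For same-length 12-mers this reduces to Hamming identity, and random
12-mers essentially never collide at the 0.8 threshold.

Target-unrelated peptide (TUP) screening is an exact-sequence lookup in a
user-supplied local table of (peptide, target) records; a peptide
recovered by four or more entirely different targets is flagged. Online
mimotope databases are deliberately not queried.

Balanced sub-datasets: `n_pairs × |positives|` negatives are sampled
without replacement (seeded) and partitioned into disjoint groups; each
group is paired with the full positive set. The canonical shape is 80
positives vs 800 sampled negatives → ten 80+80 sub-datasets. The
partition is random because the original partitioning rule is not
documented; the seed is recorded in every output.

## Sequence encoding (519 dimensions)

`AAC(20) | DPC(400) | PseAAC(24) | CKSAAGP(75)`, concatenated in that
order with stable feature names. Order stability is part of the model
contract because submodels persist selected feature *indices*.

- AAC: residue counts / L, alphabetical order.
- DPC: dipeptide counts / (L − 1), alphabetical double loop.
- PseAAC (type 1, λ = 4, ω = 0.4): residue frequencies augmented by λ
  sequence-order correlation factors. Three residue properties
  (hydrophobicity, hydrophilicity, side-chain mass; Chou's 2001 tables,
  shipped in source) are standardized to zero mean / unit variance over
  the 20 residues (population statistics); the correlation function is
  the mean squared difference of the standardized properties; the full
  24-vector is jointly normalized to sum to 1. λ = 4 suits short 12-mer
  training peptides (λ must be < L).
- CKSAAGP: the 20 residues partition into five physicochemical groups
  (aliphatic GAVLMI, aromatic FYW, positive KRH, negative DE, uncharged
  STCPNQ); for k = 0, 1, 2 the 25 ordered group-pair counts at gap k are
  divided by L − (k + 1). Each k-block therefore sums to 1.

Sequences must use the 20 standard letters, be at most 50 residues
(library inclusion criterion) and at least 5 (so every sub-descriptor is
defined).

## Feature selection and scaling

Five filter scores are provided: absolute Pearson correlation (default —
the best performer in model selection), Fisher-style F-score, and three
contingency-based scores (chi-square, information gain, plug-in mutual
information) computed after equal-width binning into B = 5 bins over each
feature's range. Under shared binning, information gain and plug-in
mutual information coincide numerically; both names are kept for
interface completeness. Constant features score 0 everywhere.

The top 160 features are kept (ties to the lower index) — 160 matching
the 160 peptides of a balanced sub-dataset — then MinMax-scaled to
[0, 1]; at application time out-of-range values are clamped and constant
features map to 0. By default both selection and scaling are re-fitted
inside every cross-validation training fold (leakage-safe); the
`legacy_selection` / `legacy_scaling` flags reproduce the variant that
fits once on the whole sub-dataset, since some AutoML toolchains do so.

## Ensemble SVM and averaging voting

Per sub-dataset: encode → select/scale → exhaustive grid search of the
RBF-SVM over the canonical LIBSVM grid (c ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, steps
of 2²) maximizing mean stratified 5-fold CV accuracy, ties resolved
toward smaller c then smaller γ; the final SVM is refitted on the whole
sub-dataset with Platt-scaled probabilities (a sigmoid fitted to
cross-validated decision values, then the SVC refitted on all data — the
LIBSVM probability procedure, implemented via scikit-learn's sigmoid
`CalibratedClassifierCV`).

Per-fold evaluation metrics use decision-sign label predictions for the
scalar metrics and decision values for AUROC/AUPRC. The Platt sigmoid is
a monotone map of the decision value, so ranking metrics are unchanged by
it when it is well conditioned; on degenerate hyperparameter plateaus
(heavily underfit SVMs whose cross-validated decision values are numerical
noise) a nested sigmoid fit can invert, so evaluation deliberately stays
on the decision scale while probabilities are reserved for what they are
needed for: ensemble averaging.

Prediction: each submodel applies its own feature subset, scaler and SVM;
the ensemble probability is the arithmetic mean; `votes` counts submodels
at or above the threshold; the final call is `binder ⇔ mean ≥ tp`
(inclusive). Default tp = 0.5; tp = 0.55 is the recommended operating
point, trading a little sensitivity for substantially better rejection of
non-binders. Raising tp can never increase the number of predicted
binders.

Models persist as a single joblib archive with a format-version string;
loading a mismatched version fails loudly.

## Synthetic data

The benchmark generator emulates the canonical study shape (80 positives,
800 negatives, 12-mers): positives carry a six-anchor position-weight
motif (W·H·Y·P·D·F at alternating positions, typical
aromatic/proline/charged anchors) mixed into a uniform background with
strength `separation ∈ [0, 1]`; at 1.0 the anchors are fixed and classes
are strongly separable, at 0.0 positives are background. The selection
simulator draws library abundances from a symmetric Dirichlet
(concentration 1.0), multiplies planted binders' weights by the
enrichment factor once per target-selection round (R1 and R2-target;
round-2 control arms reselect the round-1 pool and receive replicate
noise only), applies per-replicate lognormal weight jitter (σ = 0.2), and
samples multinomial read counts at the configured depth. Default layout:
R0 ×3, R1 ×3, R2-target ×6, beads ×3, unrelated ×3; 5000-peptide library,
10⁵ reads/sample, factor 10.

What passing tests show: the pipeline recovers planted abundance signal
and learns motif-defined sequence classes. What they do not show:
robustness to amplification bias, sequencing error, propagation-advantage
parasites, or the much weaker and more heterogeneous signal of real
selection data — real-data performance must be established on real
selections.

## Numerical and design choices

- ppm normalization (count / column total × 10⁶) stands in for the
  unspecified "normalized abundance"; any per-sample scale factor cancels.
- Enrichment p-values are uncorrected by design (the operating criterion
  is a raw threshold); users needing FDR control can apply it to the
  output table.
- Metric ratios with zero denominators return 0 with a `RuntimeWarning`
  instead of NaN so fold averaging never propagates NaN. AUROC is the
  Mann–Whitney rank statistic (ties count ½); AUPRC is step-wise average
  precision with no interpolation.
- Grid-search fold assignment is seeded and shared across the grid, so
  training is bit-reproducible given (data, seed).
- Hyperparameters are searched once per sub-dataset (on features selected
  from the whole sub-dataset); fold metrics are then computed with
  leakage-safe per-fold selection at the chosen (c, γ). Searching inside
  every fold would square the SVM-fit count for little benefit at these
  sample sizes.
- Problem sizes in the test and acceptance runs are the canonical study
  conditions themselves (80/800 benchmark, 5000-peptide simulated library
  at 10⁵ reads/sample, 20 simulation seeds), which run comfortably on a
  single CPU.

## Known limitations

- The FASTQ insert-extraction rules (exact flank match, configurable
  insert length, mean-Phred ≥ 20 over the insert) are this package's own
  documented convention; read loss is tolerated by the downstream
  ratio/p-value statistics.
- Greedy redundancy removal is exact but quadratic; it is intended for
  curated training sets, not million-read de-duplication.
- Only the SVM backend is provided for the ensemble; the classifier is
  pluggable behind `SubmodelClassifier` for other backends.
- TUP screening is exact-match only; mimotope-similarity matching is out
  of scope.
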