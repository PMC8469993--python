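# Methods

## Problem and model

A non-synonymous SNP substitutes one amino acid in a protein; the task is to
score whether the substitution is deleterious. The predictor rests on two
observations: deleterious substitutions concentrate at evolutionarily
conserved positions, and at positions involved in ligand binding, where they
can abolish function without destabilising the fold. Both signals are
computed purely from sequence.

Inputs per mutation are four MSAs — wild-type and mutant sequence, each
aligned by two complementary sources (an aligned multi-FASTA in the
PSI-BLAST style and an A3M in the HHblits style; the mutant MSA is the
result of re-searching the mutated sequence) — and three per-residue
binding-prediction channels (DNA, RNA, generic ligand), each a binary call
plus a propensity in [0, 1] per position. The package consumes these
artifacts; it does not run the alignment or binding-prediction tools.

## Profile construction

Each MSA becomes an L×20 position-specific probability matrix (PSPM). Per
column, the 20 standard residues are counted over all rows; gaps and the
ambiguity codes B, Z, X, U, O are excluded from both the counts and the
denominator, because the column distribution is defined over exactly the 20
standard types. Counts are smoothed with an additive pseudocount (default
1e-4 per type) so every entry is strictly positive, which keeps the KL
divergence finite; an all-gap column falls back to the uniform distribution.
No sequence weighting or redundancy filtering is applied within the MSA.

Entropies and KL divergences use the natural logarithm. Any fixed base
rescales these features uniformly and is absorbed by the classifier; nats
are the conventional default. The entropy standard deviation uses the
sample (n−1) denominator and is defined as 0 for a single-column profile;
the z-score collapses to 0 whenever σ < 1e-12 (a perfectly flat entropy
profile carries no positional contrast). BLOSUM62 ships with the package as
a text table in the standard NCBI layout, re-indexed to the package's
alphabetical residue order, and is used in its published half-bit integer
units.

Positions are 1-based along the ungapped query sequence at every public
interface. A3M rows are normalised by deleting lowercase (insertion)
characters and `.`, which restores the query-length column frame.

## Feature definitions and conventions

The 60-feature schema is fixed (names and order identical across records and
runs). Conventions where the definitions leave room:

- The four MSA-block differences are signed (wild-type minus mutant); the
  binding-block screening uses absolute shifts. The wild-type inner product
  b_k is evaluated with the wild-type residue on the wild-type profile and
  the mutant b_k with the mutant residue on the mutant profile.
- The screening argmax ranges over the channel's predicted binding positions
  (conservation of those m positions is what is being contrasted); a
  configuration switch (`screen_all_positions`) extends it to every
  position for sensitivity analyses.
- For the KL measure the screening quantity is d_KL(P_i‖Q_i) itself — it is
  already a wild-type-vs-mutant contrast — with no further differencing.
- Argmax ties break toward the smallest sequence index. Shift values within
  1e-9 of the maximum count as tied: column entropies depend only on the
  column's count multiset, so exact mathematical ties between columns are
  common, and without the tolerance the winner would be decided by
  floating-point summation order.
- A channel that predicts no binding residue (m = 0) emits the sentinel
  triple (shift 0, distance L, propensity 0) and closest-distance L. The
  sentinel keeps the vector finite and encodes "nothing predicted, nothing
  nearby" monotonically with the real features.

## Classification and evaluation

Six algorithm families are available with pinned hyperparameters: random
forest (100 trees, Gini impurity, sqrt-of-features per split, no depth cap),
Gaussian naive Bayes, logistic regression (standardised inputs, max 1000
iterations), a (100,) multilayer perceptron (standardised inputs, adam, max
300 iterations — bounded for predictable runtimes), AdaBoost over depth-1
trees (100 estimators), and XGBoost (100 trees). Pinning makes results
stable across library versions; the random forest is the default predictor.

Cross-validation uses stratified folds with a fixed seed; the headline
AUC/ACC/MCC score the pooled out-of-fold propensities, and per-fold metrics
are retained. Folding is at the record level; a protein-grouped option is
available via the `folds=` hook for leakage-sensitive analyses. The
independent-test protocol draws repeated stratified 80/20 splits and reports
median ACC, AUC and MCC over repeats. AUC is computed by average ranks
(Mann–Whitney form, equivalent to the trapezoidal ROC area with ties); MCC
returns 0 when any confusion-matrix marginal is 0. The decision cutoff
sweeps midpoints between consecutive sorted unique propensities plus the
endpoints and minimises |FPR − FNR|, ties broken toward 0.5. Ablation
variants retrain on the 30 MSA features (`msa_only`) or the 30 binding
features (`br_only`) alone. A paired-bootstrap AUC-difference test (10,000
resamples by default) is provided for significance statements; it is this
package's own procedure.

## Synthetic data

The generator emulates only the statistical structure the predictor
exploits, not molecular evolution. Per protein, each alignment column is
either conserved — one dominant residue carrying mass s/(s+2) for
concentration s (≈0.91 at the default s=20), remainder spread by a flat
Dirichlet — or variable, drawn from Dirichlet(5·1) whose draws sit near the
uniform distribution (mean entropy within a few percent of ln 20). Rows are
sampled independently per column with a 2% gap rate; row 0 is the modal
(query) sequence. The two alignment sources share column compositions but
sample rows independently, mimicking two tools run against different
databases. Binding channels call each position with probability
base_rate (10%) multiplied by an enrichment factor (5) at conserved columns,
capped at 1; propensities are a noisy monotone function of the call (calls
in [0.7, 1], non-calls in [0, 0.3]).

Datasets plant the label signal in both feature blocks: a deleterious
mutation is, with probability `deleterious_signal` (default 0.9), placed at
a conserved-or-binding position and its mutant alignments have a
`perturbation` fraction (0.3) of rows at the mutated column resampled to the
mutant residue; unplanted deleterious and all neutral mutations sit at
unconserved non-binding positions with mutant alignments differing from the
wild type only through the query row. Labels are flipped with probability
`label_noise` (default 2%) last. Defaults (50 proteins × 40 mutations =
2000 records, lengths 60–120, 30 alignment rows, 30% conserved columns)
give non-degenerate features and clear but imperfect class separation;
cross-validated AUC around 0.91–0.94 at the defaults and ≈1.0 with a fully
planted noise-free signal. The on-disk writer emits exactly the dialects the
readers parse and sprinkles lowercase insertion runs into the A3M files so
round-trips exercise the normalisation path.

What passing tests on this generator do and do not show: they verify the
feature arithmetic, the screening logic, the evaluation protocol, and that
the classifier recovers a conservation/binding-shaped signal end to end.
They do not certify performance on real mutation datasets, where homologs
are phylogenetically correlated, alignment depth varies by orders of
magnitude, binding predictors err systematically rather than independently,
and deleterious mechanisms extend beyond conservation and binding.

## Protocol sizes

The planted-signal, ablation, enrichment and independent-test analyses run
at n = 2000 records (the generator default); the brute-force equivalence
check compares 100 random fixtures against a naive reimplementation; the
threshold-calibration check uses 10,000 symmetric propensities. These sizes
give stable estimates (AUC sampling error well under 0.01) at modest cost.

## Known limitations

- PSPM columns are raw smoothed counts; profile outputs of the alignment
  tools themselves (e.g. PSSM-derived target frequencies) are not consumed.
- The mutant-MSA perturbation model is a stand-in for re-aligning the
  mutated sequence; real re-alignment can change row membership, not just
  the mutated column.
- Thin wrappers around locally installed alignment tools are out of scope;
  the package consumes their outputs.
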