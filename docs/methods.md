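# Methods

## Problem and model

The package regresses a continuous protein solubility score in [0, 1] (the
supernatant-to-total ratio of cell-free expression assays) from two inputs
per protein: an L×91 matrix of per-residue sequence-profile features, and an
L×L matrix of predicted contact probabilities. The protein is modelled as an
attributed graph G(X, A); the prediction pipeline is

1. **Adjacency construction.** Under the *full* scheme, A keeps every
   off-diagonal predicted probability. Under the *top-k* scheme, only the
   ⌊α·L⌋ non-local pairs (|i−j| > 2) with the highest probability are kept,
   weighted either by the probability (*continuous*) or by 1 (*discrete*).
   In both schemes pairs with |i−j| ≤ 2 get weight 1 unconditionally, so the
   α = 0 graph is still the connected peptide chain. α is accepted as any
   nonnegative real; the studied range is 0–7. Ties in the top-k ranking are
   broken by probability descending, then by the pair indices, making
   selection deterministic.
2. **Normalization.** Â = D̃⁻¹(A + I) with D̃ᵢᵢ = Σₖ(A + I)ᵢₖ. The diagonal
   of A is zeroed before the self-loop is added, so no node carries a double
   self-loop; every row of Â sums to 1 and is a convex combination over the
   node's neighbors and itself.
3. **Graph convolutions.** G^(l+1) = LayerNorm(ReLU(Â G^(l) W^(l))), two
   layers of output widths 256 and 64. The normalization is layer
   normalization over the feature axis with learned gain and bias, applied
   *after* the activation (the ordering is an open design point; post-
   activation was chosen and is fixed here).
4. **Readout.** T = softmax_rows(W₂ tanh(W₁ Mᵀ)) with W₁ ∈ ℝ^{q×p},
   W₂ ∈ ℝ^{r×p→q}; H = (1/r) Σₖ (T M)ₖ. Defaults r = 4 heads, q = 128
   (q is not strongly constrained by the architecture; 128 is the package
   default and configurable). The readout makes the output independent of
   residue ordering and protein length.
5. **Head.** S = sigmoid(W₃ Hᵀ + b), optionally preceded by hidden ReLU
   layers (`head_dims`; default none).

## Training

MSE loss (same minimizer as the reported RMSE), Adam (β₁ = 0.9, β₂ = 0.999),
learning rate 1e−3, up to 100 epochs, batches of 8 proteins whose per-graph
gradients are averaged — mathematically identical to per-graph evaluation.
With a validation set, early stopping monitors validation R² with patience
10 and restores the best parameters; when the validation set has fewer than
two proteins the score falls back to negative RMSE. Initialization is
Glorot-uniform with a fixed seed; a fixed seed reproduces the training
trajectory bit-identically on one platform.

Gradients are derived analytically for the whole architecture (graph
convolution, layer norm, softmax attention, sigmoid head) and implemented in
NumPy; the test suite checks every parameter block against central finite
differences at 1e−6 step. There is therefore no autodiff framework in the
dependency set.

## Evaluation protocol

`split_dataset` assigns ⌊fraction·n⌋ records to training by a seeded
shuffle (75% of 2737 gives the 2052/685 split). `cross_validate` shuffles
with each of several seeds, chunks into k contiguous folds (remainder
spread over the first n mod k folds), trains k models per seed and reports
the per-fold metric table plus mean ± std; because averaging folds before
or after seeds can differ, both aggregates are emitted. Ensembles average
member outputs, which never yields a larger RMSE than the worst member.

Metrics: RMSE; R² = 1 − SS_res/SS_tot; classification at a 0.5 threshold
applied to both vectors with ≥ counting as soluble (ties to positive);
precision, recall, F1 with zero-denominator cases reported as 0 with a
warning; AUC by the rank statistic with midpoint handling of ties
(scikit-learn's implementation, cross-checked in tests against a pairwise
Mann–Whitney oracle). Constant actuals make R² undefined (NaN, with a
warning), single-class actuals make AUC undefined.

## Structure-derived contacts

`contact_map_from_structure` marks residue pairs whose Cα distance is
*strictly* below the cutoff (default 7.5 Å) as contacts, counting all
unordered pairs including short-range ones; the PDB reader takes CA atoms
of the first model and a single chain (first chain unless specified) and
keeps the first altloc of each residue. Contact-prediction quality is
scored as precision (correct predicted pairs / predicted pairs) and recall
(correct predicted pairs / actual pairs) over unordered pairs.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
surface. Defaults: lengths uniform in [30, 80]; Cα conformations from a
self-avoiding-biased random walk with exact 3.8 Å bonds (the physical
Cα–Cα virtual bond length) and a centroid-drift compaction parameter of
0.6, which yields long-range contact counts of a few per residue at the
7.5 Å cutoff — the regime of globular proteins; predicted maps blend the
true binary map with Beta(2, 5) noise at weight λ = 0.2, giving the
asymmetric low-probability false-positive mass typical of contact
predictors.

Profile features are generated as *dialect-valid file content* — integer
PSSM scores, HH-suite −1000·log₂(p) codes with `*` sentinels, SPIDER3 rows
with angles in degrees — and the in-memory feature groups are obtained by
parsing those texts with the package's own parsers. Writer/parser
round-trips are therefore exact at printed precision by construction.
BLOSUM62 and the 7 physicochemical descriptors are deterministic lookups
from the sequence.

The solubility target is planted as a *graph-dependent* linear functional:
standardize features with fixed reference statistics, average each
residue's features over its **long-range** true-contact neighbors
(|i−j| > 2; residues without such neighbors contribute zero), average over
residues, project on a fixed random unit vector, and pass the centered and
scaled result through a sigmoid. Centering/scaling constants are fitted
once per generator spec on an internal 40-protein reference cohort drawn
from reserved seeds, so planted logits have mean 0 and standard deviation
`logit_spread` (default 1.3, spreading targets over most of (0, 1)).
Because the signal lives on long-range contacts, a model trained on the
chain-only (α = 0) graph can exploit only the part of the signal correlated
with unweighted feature averages, and the full contact graph should—and
in the recovery experiment does—outperform it.

What the generator does *not* emulate: evolutionary correlation structure in
profiles (PSSM/HMM values are i.i.d. draws, not alignments), realistic
secondary-structure geometry, contact-predictor error correlations, or any
sequence–structure consistency between the feature groups and the
conformation. Passing tests therefore demonstrate that the pipeline's
mechanics and learning dynamics are correct, not that real-data accuracy
figures transfer.

## Recovery experiment

`recovery_experiment` simulates 400 proteins (defaults above), and for each
of five seeds splits 300/100, carves 10% of the training proteins off as an
early-stopping validation set, trains the full-graph and the α = 0 model on
identical data, and scores the held-out 100. The acceptance checks are that
the full-graph held-out R² reaches 0.5 and that the full graph beats the
contact-free graph in at least 4 of 5 seeds. These problem sizes keep the
complete experiment to a couple of minutes on one CPU.

## Numerical choices and edge cases

- Feature columns with zero training spread are centered but not divided.
- Unknown residues ('X') encode as zero rows in BLOSUM62/AAPHY7.
- HH-suite stored values decode as 2^(−v/1000); `*` and 65535 decode to 0
  (including the Neff columns, for uniformity).
- Contact-map parsers accept dense matrices, 1-based `i j p` triplets, and
  CASP-RR-like records, autodetected by column count.
- Layer-norm epsilon 1e−5; softmax rows are max-shifted for stability.
- `floor(alpha * L)` defines the edge budget; fractional α is allowed.
- Checkpoints store parameters, architecture, the fitted feature scaler and
  the edge scheme in one versioned archive.

## Known limitations

- No pretrained weights are shipped; predictions on real proteins require
  training on real labelled data plus externally computed profiles and
  contact maps (only their file formats are handled here).
- Benchmark-scale accuracy of this architecture on the eSOL *E. coli*
  dataset is not reproducible from this repository alone, since it depends
  on those external predictor outputs; the synthetic recovery experiment is
  the package's verifiable substitute for end-to-end correctness.
- Training is CPU-bound NumPy; it is sized for cohorts of hundreds of
  proteins, not tens of thousands.
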