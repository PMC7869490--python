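# contactsol

Graph-based regression of protein solubility from sequence-derived features
and predicted residue–residue contact maps.

Protein solubility — measured in cell-free expression assays as the ratio of
the supernatant fraction to the total protein fraction, a continuous value in
[0, 1] — is a major bottleneck in recombinant protein production. `contactsol`
predicts it from sequence alone by treating each protein as an attributed
graph: residues are nodes carrying sequence-profile features, and predicted
contact probabilities between residue pairs are weighted edges. This lets the
model use (predicted) structural topology without requiring a solved
structure.

## Model

For a protein of length *L*, the node-feature matrix **X** ∈ ℝ^{L×91}
concatenates five groups per residue: BLOSUM62 substitution scores (20),
physicochemical descriptors (7), PSI-BLAST PSSM (20), HH-suite profile HMM
(30), and SPIDER3-style predicted structural features (14 — SS3
probabilities, ASA, sin/cos of φ/ψ/θ/τ, half-sphere exposures). Columns are
standardized with training-set statistics.

The predicted contact map **A** ∈ [0,1]^{L×L} becomes the adjacency either of
a fully connected graph weighted by the probabilities, or of a sparse graph
keeping only the ⌊α·L⌋ highest-probability non-local pairs (weighted by
probability or set to 1); residues with |i−j| ≤ 2 are always connected with
weight 1. Propagation uses the degree-normalized form with self-loops,
Â = D̃⁻¹(A + I), whose rows each sum to 1. The network stacks graph
convolutions

&nbsp;&nbsp;&nbsp;&nbsp;G^(l+1) = LayerNorm(ReLU(Â G^(l) W^(l)))

(two layers, widths 256 and 64), pools the residue embeddings **M** ∈ ℝ^{L×64}
with a multi-head self-attention readout

&nbsp;&nbsp;&nbsp;&nbsp;T = softmax(W₂ tanh(W₁ Mᵀ)), &nbsp; H = (1/r) Σₖ (T M)ₖ

(r = 4 heads), and maps the fixed-width embedding **H** to a solubility score
S = sigmoid(W₃ Hᵀ + b) ∈ (0, 1). Training minimizes mean squared error with
Adam; evaluation reports RMSE, R², and threshold-0.5 classification metrics
(accuracy, precision, recall, F1, AUC). The evaluation protocol includes
fivefold cross-validation repeated over five fold seeds and ensembling by
averaging fold-model outputs.

The forward **and** backward passes are implemented in plain NumPy with
analytic gradients (verified against finite differences in the test suite),
so the package has no deep-learning-framework dependency.

Because real training data requires external predictors (PSI-BLAST, HHblits,
SPIDER3, a contact predictor) over large sequence databases, the package
ships a first-class synthetic generator that emulates every input — including
the external file dialects — with solubility targets planted on long-range
contact neighborhoods, so the entire pipeline is testable offline.

## Worked example

`examples/03_train_and_evaluate.py` simulates 260 proteins, trains on 200
with the full contact-weighted graph, and evaluates the 60 held-out proteins:

```text
held-out RMSE 0.138  R2 0.606  AUC 0.874
confusion at threshold 0.5: TP 24 FP 7 TN 22 FN 7
```

R² = 0.606 means the model recovered about 60% of the variance of the
planted contact-dependent solubility signal from noisy predicted maps; AUC
0.874 is the soluble/insoluble discrimination at the 0.5 cutoff. The other
examples cover feature encoding (`01`), edge schemes and adjacency
normalization (`02`), and scoring a predicted contact map against the actual
structure-derived contacts (`04`).

A thin CLI wraps the same workflows:

```sh
contactsol simulate --n 100 --seed 1 --out-dir cohort/
contactsol train --in-dir cohort/ --out-dir run/ --epochs 100
contactsol predict --fasta cohort/all.fasta --in-dir cohort/ \
    --checkpoint run/model.npz --out scores.tsv
contactsol evaluate --predictions scored.tsv --out-dir eval/
```

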