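"""Encode a short sequence into the five node-feature groups.

Builds the BLOSUM62 and physicochemical encodings directly from the
sequence, parses synthetic PSSM/HMM/SPIDER3 profile files, and assembles
the standardized L x 91 node-feature matrix.
"""

import numpy as np

from contactsol import (
    SyntheticProteinSpec,
    apply_scaler,
    assemble_features,
    fit_scaler,
    generate_synthetic_protein,
)

spec = SyntheticProteinSpec(length_range=(12, 12), seed=42)
protein = generate_synthetic_protein(spec, 0)
print(f"sequence ({protein.length} residues): {protein.sequence}")

for name, group in protein.groups.items():
    print(f"  {name:<9s} {group.values.shape[0]} x {group.values.shape[1]}")

X = assemble_features(list(protein.groups.values()))
print(f"assembled node-feature matrix: {X.X.shape[0]} x {X.X.shape[1]}")

scaler = fit_scaler([X])
X_std = apply_scaler(scaler, X)
print(f"after standardization: column means ~ "
      f"{np.abs(X_std.X.mean(axis=0)).max():.2e} (0 = centered), "
      f"first BLOSUM62 row: {X_std.X[0, :5].round(2)}")
# Each row describes one residue; the 91 columns are the Table of feature
# groups (20 BLOSUM62 + 7 physicochemical + 20 PSSM + 30 HMM + 14 SPIDER3).
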