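"""Score a predicted contact map against the actual structure.

Derives the actual Cα contact map (7.5 Å strict cutoff) from a synthetic
conformation, thresholds the noisy predicted map to its top 3*L pairs, and
reports precision and recall of the predicted edge set.
"""

import numpy as np

from contactsol import (
    SyntheticProteinSpec,
    contact_map_from_structure,
    evaluate_contact_prediction,
    generate_synthetic_protein,
)
from contactsol.graphs import top_pairs

spec = SyntheticProteinSpec(length_range=(60, 60), seed=11)
protein = generate_synthetic_protein(spec, 0)

actual = contact_map_from_structure(protein.coords, cutoff=7.5)
n_actual = int(actual.P[np.triu_indices(protein.length, 1)].sum())
print(f"actual contacts (< 7.5 Å): {n_actual} unordered pairs "
      f"over {protein.length} residues")

predicted_pairs = top_pairs(protein.predicted_map.P, 3 * protein.length)
precision, recall = evaluate_contact_prediction(predicted_pairs, actual)
print(f"top 3L predicted pairs: precision {precision:.3f}, recall {recall:.3f}")
# Precision: fraction of predicted pairs that are real contacts.
# Recall: fraction of real contacts covered by the prediction.
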