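"""Train the solubility model on a synthetic cohort and evaluate it.

Simulates 260 proteins with solubility planted on long-range contact
neighborhoods, trains on 200, and reports held-out regression and
threshold-0.5 classification metrics for the full contact graph.
Runs in about half a minute.
"""

import numpy as np

from contactsol import (
    EdgeScheme,
    ModelConfig,
    SyntheticProteinSpec,
    TrainConfig,
    build_dataset,
    compute_metrics,
    generate_cohort,
    predict_dataset,
    train,
)

spec = SyntheticProteinSpec(seed=3)
cohort = generate_cohort(260, spec, start_seed=0)
train_prot, test_prot = cohort[:200], cohort[200:]

scheme = EdgeScheme(mode="full")
train_ds, scaler = build_dataset(train_prot, scheme)
test_ds, _ = build_dataset(test_prot, scheme, scaler=scaler)

mconfig = ModelConfig(input_dim=train_ds.records[0][0].features.width)
params = train(train_ds, mconfig, TrainConfig(epochs=60, seed=1, patience=0))

preds = predict_dataset(params, mconfig, test_ds)
report = compute_metrics(preds, test_ds.targets)
print(f"held-out RMSE {report.rmse:.3f}  R2 {report.r2:.3f}  "
      f"AUC {report.auc:.3f}")
print(f"confusion at threshold 0.5: TP {report.tp} FP {report.fp} "
      f"TN {report.tn} FN {report.fn}")
# R2 well above 0 means the model recovered a large part of the planted
# contact-dependent solubility signal from the noisy predicted maps.
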