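"""End-to-end recovery experiments on synthetic cohorts.

The central check on the whole pipeline: simulate a cohort whose solubility
targets were planted on *long-range contact* neighborhoods, train the model
once with the full contact-weighted graph and once with contact edges
removed (``alpha = 0``, chain connectivity only), and compare held-out R².
A working implementation recovers most of the planted signal with contacts
and consistently less without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import EdgeScheme
from .model import ModelConfig
from .synthetic import SyntheticProteinSpec, build_dataset, generate_cohort
from .training import TrainConfig, compute_metrics, predict_dataset, train

__all__ = ["RecoveryResult", "recovery_experiment"]

FULL_SCHEME = EdgeScheme(mode="full", weighting="continuous")
NO_CONTACT_SCHEME = EdgeScheme(mode="topk", alpha=0.0, weighting="discrete")


@dataclass
class RecoveryResult:
    """Held-out performance of the full-graph and no-contact models."""

    r2_full: list[float] = field(default_factory=list)  # per training seed
    r2_no_contact: list[float] = field(default_factory=list)
    rmse_full: list[float] = field(default_factory=list)

    @property
    def wins(self) -> int:
        """Seeds where the full graph beat the contact-free graph."""
        return sum(f > n for f, n in zip(self.r2_full, self.r2_no_contact))

    @property
    def n_seeds(self) -> int:
        return len(self.r2_full)


def _train_and_score(train_prot, test_prot, scheme, mconfig, tconfig,
                     val_fraction=0.1):
    train_ds, scaler = build_dataset(train_prot, scheme)
    test_ds, _ = build_dataset(test_prot, scheme, scaler=scaler)
    n_val = max(1, int(len(train_ds) * val_fraction))
    rng = np.random.default_rng(tconfig.seed)
    perm = rng.permutation(len(train_ds))
    fit_ds = train_ds.subset(perm[n_val:])
    val_ds = train_ds.subset(perm[:n_val])
    params = train(fit_ds, mconfig, tconfig, val_dataset=val_ds)
    preds = predict_dataset(params, mconfig, test_ds)
    return compute_metrics(preds, test_ds.targets)


def recovery_experiment(
    cohort_seed: int = 1,
    n_proteins: int = 400,
    n_train: int = 300,
    n_seeds: int = 5,
    spec: SyntheticProteinSpec | None = None,
    mconfig: ModelConfig | None = None,
    tconfig: TrainConfig | None = None,
) -> RecoveryResult:
    """Simulate, train both edge schemes over several seeds, score held out.

    For every training seed ``s`` the cohort is split ``n_train`` /
    ``n_proteins - n_train`` with that seed, and both models are trained on
    the same split. Returns per-seed held-out metrics.
    """
    if spec is None:
        spec = SyntheticProteinSpec(seed=cohort_seed)
    cohort = generate_cohort(n_proteins, spec, start_seed=0)
    if mconfig is None:
        f = cohort[0].feature_matrix().width
        mconfig = ModelConfig(input_dim=f)
    result = RecoveryResult()
    for s in range(1, n_seeds + 1):
        perm = np.random.default_rng(s).permutation(n_proteins)
        train_prot = [cohort[i] for i in perm[:n_train]]
        test_prot = [cohort[i] for i in perm[n_train:]]
        tcfg = tconfig if tconfig is not None else TrainConfig(seed=s)
        tcfg = TrainConfig(**{**tcfg.__dict__, "seed": s})
        m_full = _train_and_score(train_prot, test_prot, FULL_SCHEME,
                                  mconfig, tcfg)
        m_none = _train_and_score(train_prot, test_prot, NO_CONTACT_SCHEME,
                                  mconfig, tcfg)
        result.r2_full.append(m_full.r2)
        result.rmse_full.append(m_full.rmse)
        result.r2_no_contact.append(m_none.r2)
    return result
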