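"""Synthetic proteins for end-to-end testing without external predictors.

The generator emulates every input the pipeline consumes:

* a random amino-acid sequence;
* a Cα conformation from a compaction-biased self-avoiding random walk with
  exact 3.8 Å virtual bonds, whose contacts at a 7.5 Å cutoff define the
  *true* binary contact map;
* a *predicted* contact-probability map — the true map blended with
  Beta(2, 5) noise, mimicking the asymmetric false-positive mass of a real
  contact predictor;
* the five node-feature groups, written in the external file dialects
  (PSI-BLAST ASCII PSSM, HH-suite .hhm, SPIDER3 .spd33) and read back with
  the package parsers, so in-memory values and fixture files agree exactly
  at printed precision;
* a solubility target from a planted, graph-dependent function: a fixed
  random linear functional of the per-protein mean of each residue's
  *long-range-contact* neighborhood feature average, passed through a
  sigmoid. Because the planted signal lives on long-range contacts, a model
  deprived of contact edges cannot fully recover it.

Everything is deterministic given the spec and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    AMINO_ACIDS,
    FeatureGroup,
    NodeFeatureMatrix,
    assemble_features,
    encode_aaphy7,
    encode_blosum62,
    fit_scaler,
    apply_scaler,
    parse_profile,
)
from .graphs import ContactMap, EdgeScheme, build_contact_graph
from .training import SolubilityDataset

__all__ = [
    "SyntheticProteinSpec",
    "SyntheticProtein",
    "generate_conformation",
    "generate_synthetic_protein",
    "generate_cohort",
    "write_fixture_files",
    "write_cohort",
    "build_dataset",
]

_SS_LETTERS = "CEH"
_MIN_SELF_DIST = 3.4  # Å, clash distance for the self-avoidance bias
_HHM_STAR = -1  # sentinel for '*' fields in stored .hhm codes


@dataclass
class SyntheticProteinSpec:
    """Study conditions for the generator.

    ``compaction`` is the strength of the drift toward the running centroid
    (0 = pure random walk, more = more globular, hence more long-range
    contacts). ``noise_level`` is the blend weight of Beta(2, 5) noise in
    the predicted map. ``logit_spread`` is the standard deviation of the
    planted logit, controlling how much targets spread over (0, 1).
    """

    length_range: tuple[int, int] = (30, 80)
    bond_length: float = 3.8
    compaction: float = 0.6
    contact_cutoff: float = 7.5
    noise_level: float = 0.2
    logit_spread: float = 1.3
    planted_neighborhood: str = "long_range"  # or "contact" (incl. chain)
    seed: int = 0
    _calibration: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.length_range[0] < 3:
            raise ValueError("minimum length must be >= 3")
        if not (0 <= self.noise_level < 1):
            raise ValueError("noise_level must be in [0, 1)")
        if self.planted_neighborhood not in ("long_range", "contact"):
            raise ValueError(f"unknown neighborhood {self.planted_neighborhood!r}")


@dataclass
class SyntheticProtein:
    """One generated protein with all pipeline inputs and its target."""

    identifier: str
    sequence: str
    groups: dict[str, FeatureGroup]
    coords: np.ndarray
    true_map: ContactMap
    predicted_map: ContactMap
    target: float
    file_texts: dict[str, str]  # fixture file contents keyed by kind

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_matrix(self) -> NodeFeatureMatrix:
        return assemble_features(list(self.groups.values()))


# ---------------------------------------------------------------------------
# conformation


def generate_conformation(L: int, spec: SyntheticProteinSpec,
                          seed: int) -> np.ndarray:
    """Cα trace of a compaction-biased self-avoiding random walk.

    Consecutive residues are exactly ``bond_length`` apart; candidate steps
    that clash (< 3.4 Å to a non-adjacent placed residue) are resampled a
    bounded number of times, keeping the least-clashing candidate otherwise.
    """
    if L < 2:
        raise ValueError("need L >= 2")
    rng = np.random.default_rng(seed)
    coords = np.zeros((L, 3))
    direction = _unit(rng.normal(size=3))
    coords[1] = coords[0] + spec.bond_length * direction
    for i in range(2, L):
        centroid = coords[:i].mean(axis=0)
        best, best_score = None, -np.inf
        for _ in range(30):
            drift = centroid - coords[i - 1]
            drift_n = np.linalg.norm(drift)
            if drift_n > 0:
                drift = drift / drift_n
            step = _unit(rng.normal(size=3) + spec.compaction * drift)
            cand = coords[i - 1] + spec.bond_length * step
            d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            min_d = d.min() if d.size else np.inf
            if min_d >= _MIN_SELF_DIST:
                best = cand
                break
            if min_d > best_score:
                best, best_score = cand, min_d
        coords[i] = best
    return coords


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# file-dialect encoders (fixture writers' in-memory form)


def _format_pssm(sequence: str, scores: np.ndarray) -> str:
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    for i, aa in enumerate(sequence):
        ints = " ".join(f"{int(v):4d}" for v in scores[i])
        pct = " ".join("   0" for _ in range(20))
        lines.append(f"{i + 1:5d} {aa} {ints} {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda"]
    return "\n".join(lines) + "\n"


def _hhm_code(p: float) -> int:
    """HH-suite encoding of a probability: -1000*log2(p), '*' for ~0."""
    if p <= 0 or -1000.0 * math.log2(p) > 20000:
        return _HHM_STAR
    return int(round(-1000.0 * math.log2(p)))


def _format_hhm(sequence: str, codes: np.ndarray) -> str:
    lines = [
        "HHsearch 1.5",
        "NAME  synthetic profile",
        f"LENG  {len(sequence)} match states",
        "#",
        "NULL   " + " ".join(["3000"] * 20),
        "HMM    " + "\t".join(AMINO_ACIDS),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(sequence):
        em = "\t".join(_code_str(c) for c in codes[i, :20])
        tr = "\t".join(_code_str(c) for c in codes[i, 20:])
        lines.append(f"{aa} {i + 1}\t{em}\t{i + 1}")
        lines.append("\t" + tr)
        lines.append("")
    lines.append("//")
    return "\n".join(lines) + "\n"


def _code_str(c: int) -> str:
    return "*" if c == _HHM_STAR else str(int(c))


def _format_spd33(sequence: str, fields: np.ndarray, ss: str) -> str:
    # columns: index AA SS ASA Phi Psi Theta Tau HSEa_up HSEa_down P(C) P(E) P(H)
    lines = ["# index AA SS ASA Phi Psi Theta(i-1=>i+1) Tau(i-2=>i+2) "
             "HSE_alpha_up HSE_alpha_down P(C) P(E) P(H)"]
    for i, aa in enumerate(sequence):
        asa, phi, psi, theta, tau, hu, hd, pc, pe, ph = fields[i]
        lines.append(
            f"{i + 1} {aa} {ss[i]} {asa:.3f} {phi:.1f} {psi:.1f} {theta:.1f} "
            f"{tau:.1f} {hu:.3f} {hd:.3f} {pc:.3f} {pe:.3f} {ph:.3f}"
        )
    return "\n".join(lines) + "\n"


def _format_contact_triplets(P: np.ndarray) -> str:
    L = P.shape[0]
    lines = [
        f"{i + 1} {j + 1} {P[i, j]:.6f}"
        for i in range(L)
        for j in range(i + 1, L)
        if P[i, j] > 0
    ]
    # keep at least one record so the file is parseable even for a zero map
    if not lines:
        lines = [f"1 2 {0.0:.6f}"]
    return "\n".join(lines) + "\n"


def _format_fasta(identifier: str, sequence: str) -> str:
    body = "\n".join(sequence[i:i + 60] for i in range(0, len(sequence), 60))
    return f">{identifier}\n{body}\n"


# ---------------------------------------------------------------------------
# generation


def _raw_feature_files(sequence: str, rng: np.random.Generator):
    """Generate dialect-valid profile contents for a sequence."""
    L = len(sequence)
    pssm_scores = np.clip(np.round(rng.normal(0.0, 3.0, size=(L, 20))), -12, 12)
    emissions = rng.dirichlet(np.full(20, 0.5), size=L)
    transitions = rng.uniform(0.05, 1.0, size=(L, 10))
    hhm_codes = np.empty((L, 30), dtype=int)
    for i in range(L):
        hhm_codes[i, :20] = [_hhm_code(p) for p in emissions[i]]
        hhm_codes[i, 20:] = [_hhm_code(p) for p in transitions[i]]
    ss_idx = rng.integers(0, 3, size=L)
    ss = "".join(_SS_LETTERS[k] for k in ss_idx)
    ss3 = rng.dirichlet(np.ones(3), size=L)
    spd_fields = np.column_stack([
        np.round(rng.uniform(0.0, 1.0, size=L), 3),  # ASA
        np.round(rng.uniform(-180.0, 180.0, size=(L, 4)), 1),  # phi psi theta tau
        np.round(rng.uniform(0.0, 1.0, size=(L, 2)), 3),  # HSE up/down
        np.round(ss3, 3),  # P(C) P(E) P(H)
    ])
    texts = {
        "pssm": _format_pssm(sequence, pssm_scores),
        "hhm": _format_hhm(sequence, hhm_codes),
        "spd33": _format_spd33(sequence, spd_fields, ss),
    }
    return texts


def _protein_inputs(spec: SyntheticProteinSpec, seed: int, identifier: str,
                    stream: int = 1):
    """Sequence, profile files, conformation and contact maps (no target)."""
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, stream, seed]))
    L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    texts = _raw_feature_files(sequence, rng)
    # parse the formatted files back so memory and fixtures agree exactly
    groups = {
        "BLOSUM62": encode_blosum62(sequence),
        "AAPHY7": encode_aaphy7(sequence),
        "PSSM": parse_profile("PSSM", texts["pssm"], expected_length=L),
        "HMM": parse_profile("HMM", texts["hhm"], expected_length=L),
        "SPIDER3": parse_profile("SPIDER3", texts["spd33"], expected_length=L),
    }
    conf_seed = int(rng.integers(0, 2**31 - 1))
    coords = generate_conformation(L, spec, conf_seed)
    true_map = _contacts(coords, spec.contact_cutoff)
    lam = spec.noise_level
    if lam > 0:
        noise = rng.beta(2.0, 5.0, size=(L, L))
        noise = np.triu(noise, 1)
        noise = noise + noise.T
        P = np.clip((1 - lam) * true_map.P + lam * noise, 0.0, 1.0)
    else:
        P = true_map.P.copy()
    np.fill_diagonal(P, 0.0)
    P = np.round(P, 6)  # match the precision of the triplet fixture files
    predicted_map = ContactMap(P)
    texts["contacts"] = _format_contact_triplets(predicted_map.P)
    texts["fasta"] = _format_fasta(identifier, sequence)
    return sequence, groups, coords, true_map, predicted_map, texts


def _contacts(coords: np.ndarray, cutoff: float) -> ContactMap:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    C = (dist < cutoff).astype(float)
    np.fill_diagonal(C, 0.0)
    return ContactMap(C)


def _neighborhood_mean(X_std: np.ndarray, true_map: ContactMap,
                       mode: str) -> np.ndarray:
    """Per-protein mean of each residue's contact-neighborhood average.

    ``long_range`` restricts neighborhoods to contacts with ``|i-j| > 2``;
    residues without such neighbors contribute a zero vector.
    """
    C = true_map.P.copy()
    if mode == "long_range":
        L = C.shape[0]
        idx = np.arange(L)
        C[np.abs(idx[:, None] - idx[None, :]) <= 2] = 0.0
    deg = C.sum(axis=1, keepdims=True)
    weights = np.divide(C, deg, out=np.zeros_like(C), where=deg > 0)
    return (weights @ X_std).mean(axis=0)


def _get_calibration(spec: SyntheticProteinSpec) -> dict:
    """Fixed planted-function weights and normalization for a spec.

    Fitted once per spec on an internal reference cohort (40 proteins drawn
    with reserved seeds) so targets have mean logit 0 and standard
    deviation ``logit_spread`` under the generator's own distribution.
    """
    if spec._calibration is not None:
        return spec._calibration
    n_ref = 40
    ref = [
        _protein_inputs(spec, i, f"ref_{i}", stream=2) for i in range(n_ref)
    ]
    stacked = np.vstack([assemble_features(list(g.values())).X
                         for _, g, _, _, _, _ in ref])
    mean, std = stacked.mean(axis=0), stacked.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    f = stacked.shape[1]
    w = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919])).normal(size=f)
    w /= np.linalg.norm(w)
    raw = []
    for _, groups, _, true_map, _, _ in ref:
        X_std = (assemble_features(list(groups.values())).X - mean) / std
        raw.append(w @ _neighborhood_mean(X_std, true_map,
                                          spec.planted_neighborhood))
    raw = np.array(raw)
    s = raw.std()
    cal = {
        "feature_mean": mean,
        "feature_std": std,
        "weights": w,
        "logit_center": float(raw.mean()),
        "logit_scale": float(s if s > 0 else 1.0),
    }
    spec._calibration = cal
    return cal


def planted_target(spec: SyntheticProteinSpec, groups: dict,
                   true_map: ContactMap) -> float:
    """The planted solubility: sigmoid of the calibrated linear functional."""
    cal = _get_calibration(spec)
    X_std = (assemble_features(list(groups.values())).X
             - cal["feature_mean"]) / cal["feature_std"]
    u = _neighborhood_mean(X_std, true_map, spec.planted_neighborhood)
    z = (cal["weights"] @ u - cal["logit_center"]) / cal["logit_scale"]
    return float(1.0 / (1.0 + np.exp(-z * spec.logit_spread)))


def generate_synthetic_protein(spec: SyntheticProteinSpec, seed: int,
                               identifier: str | None = None) -> SyntheticProtein:
    """One complete synthetic protein; identical seed, identical output."""
    if identifier is None:
        identifier = f"syn_{seed:05d}"
    sequence, groups, coords, true_map, predicted_map, texts = _protein_inputs(
        spec, seed, identifier
    )
    target = planted_target(spec, groups, true_map)
    return SyntheticProtein(
        identifier=identifier, sequence=sequence, groups=groups, coords=coords,
        true_map=true_map, predicted_map=predicted_map, target=target,
        file_texts=texts,
    )


def generate_cohort(n: int, spec: SyntheticProteinSpec,
                    start_seed: int = 0) -> list[SyntheticProtein]:
    """A list of ``n`` independent synthetic proteins."""
    return [
        generate_synthetic_protein(spec, start_seed + i, f"syn_{start_seed + i:05d}")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture_files(protein: SyntheticProtein, directory) -> dict[str, Path]:
    """Write FASTA, .pssm, .hhm, .spd33 and contact-triplet files.

    The package parsers recover the written numeric payload exactly (at
    printed precision) because the in-memory values were themselves parsed
    from these texts at generation time.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffixes = {"fasta": ".fasta", "pssm": ".pssm", "hhm": ".hhm",
                "spd33": ".spd33", "contacts": ".cm"}
    paths = {}
    for kind, suffix in suffixes.items():
        path = directory / f"{protein.identifier}{suffix}"
        try:
            path.write_text(protein.file_texts[kind])
        except OSError as exc:
            raise OSError(f"cannot write fixture {path}: {exc}") from exc
        paths[kind] = path
    return paths


def write_cohort(proteins: list[SyntheticProtein], directory) -> Path:
    """Write fixture files for every protein plus a manifest CSV."""
    directory = Path(directory)
    for p in proteins:
        write_fixture_files(p, directory)
    manifest = pd.DataFrame(
        {"identifier": [p.identifier for p in proteins],
         "length": [p.length for p in proteins],
         "target": [p.target for p in proteins]}
    )
    path = directory / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# dataset assembly


def build_dataset(
    proteins: list[SyntheticProtein],
    scheme: EdgeScheme,
    scaler=None,
):
    """Assemble a :class:`SolubilityDataset` under an edge scheme.

    When ``scaler`` is None a new one is fitted on these proteins (training
    use); otherwise the given (train-fitted) scaler is applied.
    """
    matrices = [p.feature_matrix() for p in proteins]
    if scaler is None:
        scaler = fit_scaler(matrices)
    records = []
    for p, m in zip(proteins, matrices):
        X = apply_scaler(scaler, m)
        graph = build_contact_graph(p.predicted_map, X, scheme, p.identifier)
        records.append((graph, p.target, p.identifier))
    return SolubilityDataset(records), scaler
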