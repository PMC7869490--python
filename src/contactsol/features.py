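"""Per-residue node features: encoders, profile parsers, assembly, scaling.

A protein is represented by five feature groups concatenated along the
column axis in a fixed canonical order:

====================  ====  =================================================
group                 dims  source
====================  ====  =================================================
BLOSUM62                20  substitution-matrix row of each residue
AAPHY7                   7  physicochemical descriptors (Meiler set)
PSSM                    20  PSI-BLAST position-specific scoring matrix
HMM                     30  HH-suite profile HMM (.hhm), decoded
SPIDER3                 14  predicted SS3/ASA/torsion(sin,cos)/HSE features
====================  ====  =================================================

giving an ``L x 91`` node-feature matrix for a protein of length ``L``.
Columns are standardized to zero mean / unit variance with statistics fitted
over all residues of the training set (:class:`FeatureScaler`).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "GROUP_DIMS",
    "GROUP_ORDER",
    "AMINO_ACIDS",
    "FeatureGroup",
    "NodeFeatureMatrix",
    "FeatureScaler",
    "ProfileParseError",
    "encode_blosum62",
    "encode_aaphy7",
    "parse_profile",
    "assemble_features",
    "fit_scaler",
    "apply_scaler",
]

#: canonical one-letter order used for BLOSUM62 and PSSM columns
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

GROUP_ORDER = ("BLOSUM62", "AAPHY7", "PSSM", "HMM", "SPIDER3")
GROUP_DIMS = {"BLOSUM62": 20, "AAPHY7": 7, "PSSM": 20, "HMM": 30, "SPIDER3": 14}

# Meiler 7-descriptor set, reordered to
# (steric, hydrophobicity, volume, polarizability, isoelectric point,
#  helix probability, sheet probability).
_AAPHY7 = {
    "A": (1.28, 0.31, 1.00, 0.05, 6.11, 0.42, 0.23),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "V": (3.67, 1.22, 3.00, 0.14, 6.02, 0.27, 0.49),
    "L": (2.59, 1.70, 4.00, 0.19, 6.04, 0.39, 0.31),
    "I": (4.19, 1.80, 4.00, 0.19, 6.04, 0.30, 0.45),
    "F": (2.94, 1.79, 5.89, 0.29, 5.67, 0.30, 0.38),
    "Y": (2.94, 0.96, 6.47, 0.30, 5.66, 0.25, 0.41),
    "W": (3.21, 2.25, 8.08, 0.41, 5.94, 0.32, 0.42),
    "T": (3.03, 0.26, 2.60, 0.11, 5.60, 0.21, 0.36),
    "S": (1.31, -0.04, 1.60, 0.06, 5.70, 0.20, 0.28),
    "R": (2.34, -1.01, 6.13, 0.29, 10.74, 0.36, 0.25),
    "K": (1.89, -0.99, 4.77, 0.22, 9.99, 0.32, 0.27),
    "H": (2.99, 0.13, 4.66, 0.23, 7.69, 0.27, 0.30),
    "D": (1.60, -0.77, 2.78, 0.11, 2.95, 0.25, 0.20),
    "E": (1.56, -0.64, 3.78, 0.15, 3.09, 0.42, 0.21),
    "N": (1.60, -0.60, 2.95, 0.13, 6.52, 0.21, 0.22),
    "Q": (1.56, -0.22, 3.95, 0.18, 5.65, 0.36, 0.25),
    "M": (2.35, 1.23, 4.43, 0.22, 5.71, 0.38, 0.32),
    "P": (2.67, 0.72, 2.72, 0.00, 6.80, 0.13, 0.34),
    "C": (1.77, 1.54, 2.43, 0.13, 6.35, 0.17, 0.41),
}

_blosum62_rows: dict[str, np.ndarray] | None = None


def _blosum62_table() -> dict[str, np.ndarray]:
    """Rows of the canonical BLOSUM62 matrix, keyed by residue letter."""
    global _blosum62_rows
    if _blosum62_rows is None:
        mat = substitution_matrices.load("BLOSUM62")
        _blosum62_rows = {
            aa: np.array([mat[aa, bb] for bb in AMINO_ACIDS], dtype=float)
            for aa in AMINO_ACIDS
        }
    return _blosum62_rows


class ProfileParseError(ValueError):
    """Raised when a profile file cannot be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class FeatureGroup:
    """One named block of per-residue features (``L x d``)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in GROUP_DIMS:
            raise ValueError(f"unknown feature group {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != GROUP_DIMS[self.name]:
            raise ValueError(
                f"group {self.name} must have {GROUP_DIMS[self.name]} columns, "
                f"got shape {self.values.shape}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class NodeFeatureMatrix:
    """Concatenated node features ``X`` (``L x f``) in canonical group order."""

    X: np.ndarray
    group_order: tuple[str, ...]
    standardized: bool = False

    @property
    def length(self) -> int:
        return self.X.shape[0]

    @property
    def width(self) -> int:
        return self.X.shape[1]


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("sequence must be nonempty")
    seq = seq.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in AMINO_ACIDS and aa != "X":
            raise ValueError(f"invalid residue {aa!r} at position {pos}")
    return seq


def encode_blosum62(seq: str) -> FeatureGroup:
    """Encode each residue as its BLOSUM62 substitution row.

    Unknown residues ('X') map to an all-zero row so they contribute
    nothing after centering.
    """
    seq = _validate_sequence(seq)
    table = _blosum62_table()
    rows = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        if aa != "X":
            rows[i] = table[aa]
    return FeatureGroup("BLOSUM62", rows)


def encode_aaphy7(seq: str) -> FeatureGroup:
    """Encode each residue with 7 physicochemical descriptors: steric
    parameter, hydrophobicity, volume, polarizability, isoelectric point,
    helix probability and sheet probability. 'X' maps to zeros."""
    seq = _validate_sequence(seq)
    rows = np.zeros((len(seq), 7))
    for i, aa in enumerate(seq):
        if aa != "X":
            rows[i] = _AAPHY7[aa]
    return FeatureGroup("AAPHY7", rows)


# ---------------------------------------------------------------------------
# profile parsers


def _parse_pssm(text: str) -> np.ndarray:
    rows = []
    in_body = False
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not in_body:
            # body starts at the double header of 40 residue letters
            if stripped and stripped.split()[0] == "A" and len(stripped.split()) >= 20:
                in_body = True
            continue
        if not stripped:
            break
        tokens = stripped.split()
        if tokens[0] in ("Lambda", "K", "Standard", "PSI", "Gapped"):
            break
        if len(tokens) < 22:
            raise ProfileParseError(
                f"PSSM row has {len(tokens)} fields, expected at least 22", lineno
            )
        if not tokens[0].isdigit():
            raise ProfileParseError(f"expected residue index, got {tokens[0]!r}", lineno)
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise ProfileParseError(f"non-numeric PSSM field: {exc}", lineno) from None
    if not rows:
        raise ProfileParseError("no PSSM data rows found")
    return np.array(rows)


def _decode_hhm_value(token: str, lineno: int) -> float:
    """HH-suite stores -1000*log2(p); decode back to a probability."""
    if token == "*":
        return 0.0
    try:
        v = float(token)
    except ValueError:
        raise ProfileParseError(f"non-numeric HMM field {token!r}", lineno) from None
    if v == 65535:
        return 0.0
    return 2.0 ** (-v / 1000.0)


def _parse_hhm(text: str) -> np.ndarray:
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith("HMM"):
            start = i
            break
    if start is None:
        raise ProfileParseError("no 'HMM' header found in .hhm file")
    # skip: HMM header line, transition header line, begin-state transition line
    i = start + 3
    rows = []
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("//"):
            break
        if not line:
            i += 1
            continue
        tokens = line.split()
        if len(tokens) < 22:
            raise ProfileParseError(
                f"HMM match line has {len(tokens)} fields, expected >= 22", i + 1
            )
        emissions = [_decode_hhm_value(t, i + 1) for t in tokens[2:22]]
        if i + 1 >= len(lines):
            raise ProfileParseError("truncated .hhm: missing transition line", i + 1)
        trans_tokens = lines[i + 1].split()
        if len(trans_tokens) != 10:
            raise ProfileParseError(
                f"HMM transition line has {len(trans_tokens)} fields, expected 10",
                i + 2,
            )
        transitions = [_decode_hhm_value(t, i + 2) for t in trans_tokens]
        rows.append(emissions + transitions)
        i += 2
    if not rows:
        raise ProfileParseError("no HMM data rows found")
    return np.array(rows)


def _parse_spd33(text: str, angle_dialect: str = "degrees") -> np.ndarray:
    """SPIDER3 .spd33 rows -> 14 features per residue.

    Column layout of the file: index, AA, SS, ASA, Phi, Psi, Theta, Tau,
    HSE-up, HSE-down, P(C), P(E), P(H).  The four torsion angles are expanded
    to sine/cosine at parse time when stored in degrees (``angle_dialect=
    'degrees'``); with ``'sincos'`` the file already holds the 8 values.
    Output order: P(C), P(E), P(H), ASA, sin/cos of phi, psi, theta, tau,
    HSE-up, HSE-down.
    """
    if angle_dialect not in ("degrees", "sincos"):
        raise ValueError(f"unknown angle dialect {angle_dialect!r}")
    n_cols = 13 if angle_dialect == "degrees" else 17
    rows = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < n_cols:
            raise ProfileParseError(
                f"SPIDER3 row has {len(tokens)} fields, expected {n_cols}", lineno
            )
        try:
            asa = float(tokens[3])
            if angle_dialect == "degrees":
                angles = [float(t) for t in tokens[4:8]]
                hse = [float(t) for t in tokens[8:10]]
                probs = [float(t) for t in tokens[10:13]]
                sincos = []
                for a in angles:
                    rad = math.radians(a)
                    sincos += [math.sin(rad), math.cos(rad)]
            else:
                sincos = [float(t) for t in tokens[4:12]]
                hse = [float(t) for t in tokens[12:14]]
                probs = [float(t) for t in tokens[14:17]]
        except ValueError as exc:
            raise ProfileParseError(f"non-numeric SPIDER3 field: {exc}", lineno) from None
        rows.append(probs + [asa] + sincos + hse)
    if not rows:
        raise ProfileParseError("no SPIDER3 data rows found")
    return np.array(rows)


def parse_profile(kind: str, text: str, expected_length: int | None = None,
                  angle_dialect: str = "degrees") -> FeatureGroup:
    """Parse a PSSM / HMM / SPIDER3 profile file into a feature group.

    Parameters
    ----------
    kind:
        One of ``"PSSM"`` (PSI-BLAST ASCII), ``"HMM"`` (HH-suite .hhm) or
        ``"SPIDER3"`` (.spd33).
    text:
        File content.
    expected_length:
        If given, a row-count mismatch raises :class:`ProfileParseError`.
    angle_dialect:
        SPIDER3 only; whether torsion angles are stored in degrees (expanded
        to sin/cos here) or already as the 8 sine/cosine columns.
    """
    if kind == "PSSM":
        values = _parse_pssm(text)
    elif kind == "HMM":
        values = _parse_hhm(text)
    elif kind == "SPIDER3":
        values = _parse_spd33(text, angle_dialect)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if expected_length is not None and values.shape[0] != expected_length:
        raise ProfileParseError(
            f"{kind} has {values.shape[0]} rows but sequence length is "
            f"{expected_length}"
        )
    return FeatureGroup(kind, values)


# ---------------------------------------------------------------------------
# assembly and scaling


def assemble_features(groups: list[FeatureGroup]) -> NodeFeatureMatrix:
    """Concatenate feature groups column-wise in canonical order.

    Input order is irrelevant; output columns always follow
    :data:`GROUP_ORDER`. All groups must share the same number of residues
    and each group may appear at most once.
    """
    if not groups:
        raise ValueError("at least one feature group is required")
    by_name: dict[str, FeatureGroup] = {}
    for g in groups:
        if g.name in by_name:
            raise ValueError(f"duplicate feature group {g.name!r}")
        by_name[g.name] = g
    lengths = {g.length for g in groups}
    if len(lengths) != 1:
        raise ValueError(f"feature groups disagree on length: {sorted(lengths)}")
    order = tuple(n for n in GROUP_ORDER if n in by_name)
    X = np.hstack([by_name[n].values for n in order])
    return NodeFeatureMatrix(X=X, group_order=order, standardized=False)


@dataclass
class FeatureScaler:
    """Column-wise standardization statistics fitted on training residues.

    Columns with zero spread are centered but not divided.
    """

    mean_: np.ndarray
    std_: np.ndarray
    group_order: tuple[str, ...] = field(default=GROUP_ORDER)

    @property
    def width(self) -> int:
        return self.mean_.shape[0]


def fit_scaler(training_matrices: list[NodeFeatureMatrix]) -> FeatureScaler:
    """Fit per-column mean/std over all residues of all training proteins."""
    if not training_matrices:
        raise ValueError("need at least one training matrix")
    widths = {m.width for m in training_matrices}
    if len(widths) != 1:
        raise ValueError(f"training matrices disagree on width: {sorted(widths)}")
    stacked = np.vstack([m.X for m in training_matrices])
    if stacked.shape[0] < 2:
        raise ValueError("scaler requires at least 2 residues in total")
    return FeatureScaler(
        mean_=stacked.mean(axis=0),
        std_=stacked.std(axis=0),
        group_order=training_matrices[0].group_order,
    )


def apply_scaler(scaler: FeatureScaler, matrix: NodeFeatureMatrix) -> NodeFeatureMatrix:
    """Standardize a feature matrix with train-fitted statistics."""
    if matrix.width != scaler.width:
        raise ValueError(
            f"feature width {matrix.width} does not match scaler width {scaler.width}"
        )
    denom = np.where(scaler.std_ > 0, scaler.std_, 1.0)
    X = (matrix.X - scaler.mean_) / denom
    return NodeFeatureMatrix(X=X, group_order=matrix.group_order, standardized=True)
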