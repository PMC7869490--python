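"""Protein graphs from predicted contact maps.

A predicted contact map is a symmetric ``L x L`` matrix of contact
probabilities. It becomes the weighted adjacency of a protein graph under
one of two edge schemes:

* ``full`` — every residue pair is an edge weighted by its predicted
  probability;
* ``topk`` — only the ``floor(alpha * L)`` non-local pairs with the highest
  predicted probability are kept, weighted either by the probability
  (``continuous``) or by 1 (``discrete``).

In both schemes residues within two sequence positions of each other
(``|i - j| <= 2``) are always connected with weight 1, so even the
``alpha = 0`` graph is a connected chain. For propagation the adjacency is
degree-normalized as ``D~^-1 (A + I)``, making every row a convex
combination over a node's neighbors and itself.

The module also derives *actual* contact maps from Cα coordinates
(default cutoff 7.5 Å) and scores a predicted edge set against them.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import NodeFeatureMatrix

__all__ = [
    "ContactMap",
    "EdgeScheme",
    "ProteinGraph",
    "build_contact_graph",
    "normalize_adjacency",
    "contact_map_from_structure",
    "evaluate_contact_prediction",
    "parse_contact_map",
    "read_ca_coordinates",
    "top_pairs",
]

_SEQ_NEIGHBOR_SEP = 2  # |i-j| <= 2 pairs are always connected


@dataclass
class ContactMap:
    """Symmetric matrix of predicted contact probabilities, zero diagonal."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"contact map must be square, got shape {P.shape}")
        if not np.allclose(P, P.T, atol=1e-8):
            raise ValueError("contact map must be symmetric")
        if P.min() < -1e-12 or P.max() > 1 + 1e-12:
            raise ValueError("contact probabilities must lie in [0, 1]")
        P = P.copy()
        np.fill_diagonal(P, 0.0)
        self.P = np.clip(P, 0.0, 1.0)

    @property
    def length(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class EdgeScheme:
    """How a predicted contact map is turned into graph edges."""

    mode: str = "full"  # "full" | "topk"
    alpha: float = 0.0  # edge budget multiplier, edges = floor(alpha * L)
    weighting: str = "continuous"  # "continuous" | "discrete"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "topk"):
            raise ValueError(f"unknown edge mode {self.mode!r}")
        if self.weighting not in ("continuous", "discrete"):
            raise ValueError(f"unknown edge weighting {self.weighting!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class ProteinGraph:
    """Node features plus weighted adjacency under a chosen edge scheme."""

    features: NodeFeatureMatrix
    A: np.ndarray
    scheme: EdgeScheme
    identifier: str = ""

    @property
    def length(self) -> int:
        return self.A.shape[0]


def _sequence_neighbor_mask(L: int) -> np.ndarray:
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    return (sep >= 1) & (sep <= _SEQ_NEIGHBOR_SEP)


def top_pairs(P: np.ndarray, budget: int) -> list[tuple[int, int]]:
    """The ``budget`` highest-probability non-local pairs (0-based, i < j).

    Pairs with ``|i - j| <= 2`` are excluded (they are always edges).
    Ties break deterministically by probability descending, then i, then j.
    """
    L = P.shape[0]
    pairs = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > _SEQ_NEIGHBOR_SEP
    ]
    pairs.sort(key=lambda ij: (-P[ij], ij[0], ij[1]))
    return pairs[:budget]


def build_contact_graph(
    cmap: ContactMap, X: NodeFeatureMatrix, scheme: EdgeScheme, identifier: str = ""
) -> ProteinGraph:
    """Apply an edge scheme to a predicted contact map.

    ``full``: every off-diagonal entry keeps its predicted probability.
    ``topk``: the ``floor(alpha * L)`` best non-local pairs are kept,
    weighted by probability (continuous) or 1 (discrete). In both modes the
    sequence neighbors ``|i - j| <= 2`` are overwritten to weight 1.
    """
    P = cmap.P
    L = cmap.length
    if X.length != L:
        raise ValueError(
            f"feature matrix has {X.length} residues but contact map has {L}"
        )
    neighbors = _sequence_neighbor_mask(L)
    if scheme.mode == "full":
        A = P.copy()
    else:
        budget = int(np.floor(scheme.alpha * L))
        A = np.zeros_like(P)
        for i, j in top_pairs(P, budget):
            w = 1.0 if scheme.weighting == "discrete" else P[i, j]
            A[i, j] = A[j, i] = w
    A[neighbors] = 1.0
    np.fill_diagonal(A, 0.0)
    return ProteinGraph(features=X, A=A, scheme=scheme, identifier=identifier)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Degree-normalize ``A`` for propagation: ``D~^-1 (A + I)``.

    Self-loops are added first, so every row sum is positive and the result
    is row-stochastic: each row is a convex combination over the node's
    neighbors and itself.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if A.min() < 0:
        raise ValueError("adjacency entries must be nonnegative")
    A_tilde = A + np.eye(A.shape[0])
    return A_tilde / A_tilde.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# structure-derived contacts


def contact_map_from_structure(coords: np.ndarray, cutoff: float = 7.5) -> ContactMap:
    """Binary contact map from Cα coordinates.

    Residues ``i != j`` are in contact iff their Euclidean distance is
    strictly below ``cutoff`` (Å).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coordinates must be L x 3, got shape {coords.shape}")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 residues")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    contacts = (dist < cutoff).astype(float)
    np.fill_diagonal(contacts, 0.0)
    return ContactMap(contacts)


def evaluate_contact_prediction(
    predicted_pairs, actual: ContactMap
) -> tuple[float, float]:
    """Precision and recall of a predicted edge set against actual contacts.

    Pairs are counted unordered. An empty predicted set yields precision 0
    with a warning; an actual map without contacts yields recall 0.
    """
    pred = {(min(i, j), max(i, j)) for i, j in predicted_pairs}
    act = {
        (i, j)
        for i in range(actual.length)
        for j in range(i + 1, actual.length)
        if actual.P[i, j] > 0
    }
    hits = len(pred & act)
    if not pred:
        warnings.warn("empty predicted contact set; precision reported as 0")
        precision = 0.0
    else:
        precision = hits / len(pred)
    recall = hits / len(act) if act else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# readers


def parse_contact_map(text: str, length: int | None = None,
                      dialect: str = "auto") -> ContactMap:
    """Read a predicted contact map from text.

    Supported dialects, autodetected unless overridden:

    * ``dense`` — whitespace-separated ``L x L`` matrix;
    * ``triplets`` — lines of ``i j probability`` (1-based, i < j);
    * ``casp`` — CASP-RR-like records ``i j d_min d_max probability``,
      ignoring header/sequence lines.

    Sparse dialects require ``length`` to size the matrix (unless the
    maximum index is taken as the length when omitted).
    """
    lines = [ln.strip() for ln in io.StringIO(text)]
    data_lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not data_lines:
        raise ValueError("empty contact map file")
    if dialect == "auto":
        tokens = data_lines[0].split()
        ncols = len(tokens)
        if ncols == 3:
            dialect = "triplets"
        elif ncols == 5:
            dialect = "casp"
        elif ncols >= 2 and len(data_lines) == ncols:
            dialect = "dense"
        else:
            # CASP files may open with PFRMAT/TARGET/sequence lines
            dialect = "casp"
    if dialect == "dense":
        rows = [[float(t) for t in ln.split()] for ln in data_lines]
        return ContactMap(np.array(rows))
    records: list[tuple[int, int, float]] = []
    for lineno, ln in enumerate(data_lines, start=1):
        tokens = ln.split()
        if dialect == "casp" and (not tokens[0].isdigit()):
            continue  # PFRMAT / TARGET / MODEL / sequence lines
        try:
            i, j = int(tokens[0]), int(tokens[1])
            p = float(tokens[-1])
        except (ValueError, IndexError):
            raise ValueError(f"bad contact record at data line {lineno}: {ln!r}") from None
        records.append((i, j, p))
    if not records:
        raise ValueError("no contact records found")
    L = length if length is not None else max(max(i, j) for i, j, _ in records)
    P = np.zeros((L, L))
    for i, j, p in records:
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"contact index ({i},{j}) outside 1..{L}")
        P[i - 1, j - 1] = P[j - 1, i - 1] = p
    return ContactMap(P)


def read_ca_coordinates(pdb_text: str, chain: str | None = None) -> np.ndarray:
    """Cα trace from PDB text: ATOM records, first model, one chain.

    ``chain=None`` takes the first chain encountered. Alternate locations
    keep the first occurrence of each residue.
    """
    coords: list[tuple[float, float, float]] = []
    seen: set[tuple[str, int, str]] = set()
    selected_chain = chain
    for line in io.StringIO(pdb_text):
        if line.startswith("ENDMDL"):
            break  # first model only
        if not line.startswith("ATOM"):
            continue
        if line[12:16].strip() != "CA":
            continue
        ch = line[21]
        if selected_chain is None:
            selected_chain = ch
        if ch != selected_chain:
            continue
        key = (ch, int(line[22:26]), line[26])
        if key in seen:
            continue
        seen.add(key)
        coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    if not coords:
        raise ValueError("no Cα ATOM records found" +
                         (f" for chain {chain!r}" if chain else ""))
    return np.array(coords)
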