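"""Attention-pooled graph convolutional network for solubility regression.

The forward model maps a protein graph (standardized node features ``X``,
degree-normalized adjacency ``A^``) to a scalar solubility in (0, 1):

1.  Stacked graph convolutions, each ``G' = LN(ReLU(A^ G W))`` with layer
    normalization over the feature axis after the activation; default two
    layers of widths 256 and 64. The last layer's output ``M`` (``L x p``)
    holds one embedding per residue.
2.  Multi-head self-attention readout: ``T = softmax_rows(W2 tanh(W1 M^T))``
    gives ``r`` weight distributions over residues (default ``r = 4`` heads,
    hidden width ``q = 128``); the graph embedding is the head average
    ``H = (1/r) sum_k (T M)_k``, a fixed ``p``-vector regardless of protein
    length — making the readout invariant to residue permutation.
3.  A linear head with sigmoid: ``S = sigmoid(W3 H^T + b)``.

Both the forward pass and the analytic backward pass are implemented here
in plain NumPy; gradients are exact (they are checked against central finite
differences in the test suite) and the whole computation is deterministic
for a fixed parameter seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .graphs import ProteinGraph, normalize_adjacency

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "init_parameters",
    "gcn_layer_forward",
    "attention_pool",
    "forward",
    "predict_solubility",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``gcn_dims`` lists the output width of every graph-convolution layer;
    the last entry ``p`` is the embedding width carried through the readout.
    ``head_dims`` lists optional hidden widths of the output perceptron
    (empty = a single linear layer).
    """

    input_dim: int
    gcn_dims: tuple[int, ...] = (256, 64)
    attention_heads: int = 4
    attention_hidden: int = 128
    head_dims: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not self.gcn_dims or any(d < 1 for d in self.gcn_dims):
            raise ValueError("gcn_dims must be a nonempty tuple of positive ints")
        if self.attention_heads < 1 or self.attention_hidden < 1:
            raise ValueError("attention dimensions must be >= 1")
        object.__setattr__(self, "gcn_dims", tuple(self.gcn_dims))
        object.__setattr__(self, "head_dims", tuple(self.head_dims))

    @property
    def n_gcn_layers(self) -> int:
        return len(self.gcn_dims)

    @property
    def embedding_dim(self) -> int:
        return self.gcn_dims[-1]


@dataclass
class ModelParameters:
    """All learned tensors; shapes follow :class:`ModelConfig`."""

    gcn_weights: list[np.ndarray]  # W^(l): f_l x f_{l+1}
    ln_gain: list[np.ndarray]  # per-layer layer-norm gain, f_{l+1}
    ln_bias: list[np.ndarray]  # per-layer layer-norm bias, f_{l+1}
    W1: np.ndarray  # q x p
    W2: np.ndarray  # r x q
    head_weights: list[np.ndarray]  # hidden head layers then final 1 x d
    head_biases: list[np.ndarray]

    def to_flat_list(self) -> list[np.ndarray]:
        return (
            self.gcn_weights + self.ln_gain + self.ln_bias
            + [self.W1, self.W2] + self.head_weights + self.head_biases
        )

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            gcn_weights=[w.copy() for w in self.gcn_weights],
            ln_gain=[g.copy() for g in self.ln_gain],
            ln_bias=[b.copy() for b in self.ln_bias],
            W1=self.W1.copy(),
            W2=self.W2.copy(),
            head_weights=[w.copy() for w in self.head_weights],
            head_biases=[b.copy() for b in self.head_biases],
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(config: ModelConfig, seed: int = 0) -> ModelParameters:
    """Glorot-uniform weights, zero biases, unit layer-norm gains."""
    rng = np.random.default_rng(seed)
    dims = (config.input_dim,) + config.gcn_dims
    gcn_weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(len(config.gcn_dims))]
    ln_gain = [np.ones(d) for d in config.gcn_dims]
    ln_bias = [np.zeros(d) for d in config.gcn_dims]
    p, q, r = config.embedding_dim, config.attention_hidden, config.attention_heads
    W1 = _glorot(rng, q, p)
    W2 = _glorot(rng, r, q)
    head_weights, head_biases = [], []
    prev = p
    for d in config.head_dims:
        head_weights.append(_glorot(rng, d, prev))
        head_biases.append(np.zeros(d))
        prev = d
    head_weights.append(_glorot(rng, 1, prev))
    head_biases.append(np.zeros(1))
    return ModelParameters(gcn_weights, ln_gain, ln_bias, W1, W2,
                           head_weights, head_biases)


# ---------------------------------------------------------------------------
# forward


def _layer_norm(R: np.ndarray, gain: np.ndarray, bias: np.ndarray):
    mu = R.mean(axis=1, keepdims=True)
    var = R.var(axis=1, keepdims=True)
    xhat = (R - mu) / np.sqrt(var + _LN_EPS)
    return xhat * gain + bias, xhat, var


def gcn_layer_forward(
    G: np.ndarray,
    A_hat: np.ndarray,
    W: np.ndarray,
    ln_gain: np.ndarray | None = None,
    ln_bias: np.ndarray | None = None,
    apply_norm: bool = True,
) -> np.ndarray:
    """One graph convolution: ``LN(ReLU(A^ G W))`` (norm optional)."""
    if G.shape[1] != W.shape[0]:
        raise ValueError(f"activation width {G.shape[1]} != weight rows {W.shape[0]}")
    if A_hat.shape[0] != G.shape[0]:
        raise ValueError("adjacency and activations disagree on L")
    R = np.maximum(A_hat @ G @ W, 0.0)
    if not apply_norm:
        return R
    out, _, _ = _layer_norm(R, ln_gain, ln_bias)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite activations in GCN layer")
    return out


def _softmax_rows(S: np.ndarray) -> np.ndarray:
    shifted = S - S.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def attention_pool(M: np.ndarray, W1: np.ndarray, W2: np.ndarray):
    """Self-attention readout.

    Returns ``(T, H)`` where ``T`` (``r x L``) holds one weight distribution
    per head (rows sum to 1) and ``H`` (``p``,) is the head-averaged pooled
    embedding ``(1/r) sum_k (T M)_k``.
    """
    if W1.shape[1] != M.shape[1]:
        raise ValueError(f"W1 expects width {W1.shape[1]}, got M width {M.shape[1]}")
    if W2.shape[1] != W1.shape[0]:
        raise ValueError("W2 columns must match W1 rows")
    U = np.tanh(W1 @ M.T)  # q x L
    T = _softmax_rows(W2 @ U)  # r x L
    H = (T @ M).mean(axis=0)  # p
    return T, H


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def forward(X: np.ndarray, A_hat: np.ndarray, params: ModelParameters,
            config: ModelConfig, keep_cache: bool = False):
    """Full forward pass; returns ``(S, T, cache)``.

    ``cache`` (when requested) holds every intermediate needed by
    :func:`backward`.
    """
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"feature width {X.shape[1]} != configured input_dim {config.input_dim}"
        )
    G = X
    layer_caches = []
    for W, gain, bias in zip(params.gcn_weights, params.ln_gain, params.ln_bias):
        Z = A_hat @ G @ W
        R = np.maximum(Z, 0.0)
        out, xhat, var = _layer_norm(R, gain, bias)
        if keep_cache:
            layer_caches.append({"G": G, "Z": Z, "xhat": xhat, "var": var})
        G = out
    M = G  # L x p
    U = np.tanh(params.W1 @ M.T)
    T = _softmax_rows(params.W2 @ U)
    H = (T @ M).mean(axis=0)
    # head: optional hidden ReLU layers, then scalar linear + sigmoid
    h = H
    head_caches = []
    for W, b in zip(params.head_weights[:-1], params.head_biases[:-1]):
        z = W @ h + b
        if keep_cache:
            head_caches.append({"h_in": h, "z": z})
        h = np.maximum(z, 0.0)
    logit = float((params.head_weights[-1] @ h + params.head_biases[-1])[0])
    S = _sigmoid(logit)
    cache = None
    if keep_cache:
        cache = {
            "A_hat": A_hat, "layers": layer_caches, "M": M, "U": U, "T": T,
            "H": H, "head": head_caches, "h_last": h, "S": S,
        }
    return S, T, cache


def backward(dS: float, params: ModelParameters, config: ModelConfig,
             cache: dict) -> ModelParameters:
    """Analytic gradients of a scalar loss given ``dS = dL/dS``.

    Returns a :class:`ModelParameters` holding the gradients (same shapes).
    """
    S = cache["S"]
    dlogit = dS * S * (1.0 - S)
    # head
    head_w_grads = [None] * len(params.head_weights)
    head_b_grads = [None] * len(params.head_biases)
    h = cache["h_last"]
    head_w_grads[-1] = dlogit * h[None, :]
    head_b_grads[-1] = np.array([dlogit])
    dh = dlogit * params.head_weights[-1][0]
    for idx in range(len(params.head_weights) - 2, -1, -1):
        hc = cache["head"][idx]
        dz = dh * (hc["z"] > 0)
        head_w_grads[idx] = np.outer(dz, hc["h_in"])
        head_b_grads[idx] = dz
        dh = params.head_weights[idx].T @ dz
    dH = dh  # p
    # attention pooling
    r = config.attention_heads
    T, M, U = cache["T"], cache["M"], cache["U"]
    dTM = np.tile(dH[None, :] / r, (r, 1))  # r x p
    dT = dTM @ M.T  # r x L
    dM = T.T @ dTM  # L x p
    # softmax rows backward
    dScore = T * (dT - (dT * T).sum(axis=1, keepdims=True))  # r x L
    dW2 = dScore @ U.T
    dU = params.W2.T @ dScore  # q x L
    dPre1 = dU * (1.0 - U**2)
    dW1 = dPre1 @ M
    dM += (params.W1.T @ dPre1).T
    # GCN layers (reverse)
    A_hat = cache["A_hat"]
    gcn_w_grads = [None] * len(params.gcn_weights)
    gain_grads = [None] * len(params.ln_gain)
    bias_grads = [None] * len(params.ln_bias)
    dOut = dM
    for l in range(len(params.gcn_weights) - 1, -1, -1):
        lc = cache["layers"][l]
        xhat, var, Z, G_in = lc["xhat"], lc["var"], lc["Z"], lc["G"]
        gain = params.ln_gain[l]
        gain_grads[l] = (dOut * xhat).sum(axis=0)
        bias_grads[l] = dOut.sum(axis=0)
        # layer-norm backward over the feature axis (per row)
        dxhat = dOut * gain
        d = xhat.shape[1]
        inv_std = 1.0 / np.sqrt(var + _LN_EPS)
        dR = (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        ) * inv_std
        dZ = dR * (Z > 0)
        AG = A_hat @ G_in
        gcn_w_grads[l] = AG.T @ dZ
        dOut = A_hat.T @ (dZ @ params.gcn_weights[l].T)
    return ModelParameters(gcn_w_grads, gain_grads, bias_grads, dW1, dW2,
                           head_w_grads, head_b_grads)


def predict_solubility(graph: ProteinGraph, params: ModelParameters,
                       config: ModelConfig, return_attention: bool = False):
    """Predict a solubility score in (0, 1) for one protein graph."""
    A_hat = normalize_adjacency(graph.A)
    S, T, _ = forward(graph.features.X, A_hat, params, config)
    if return_attention:
        return S, T
    return S


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, params: ModelParameters, config: ModelConfig,
                    scaler=None, scheme=None) -> None:
    """Serialize config + parameters (+ optional scaler and edge scheme)
    into one .npz archive so predictions are reproducible."""
    meta = {"format_version": 1, "config": asdict(config)}
    arrays: dict[str, np.ndarray] = {}
    for i, w in enumerate(params.gcn_weights):
        arrays[f"gcn_W_{i}"] = w
    for i, g in enumerate(params.ln_gain):
        arrays[f"ln_gain_{i}"] = g
        arrays[f"ln_bias_{i}"] = params.ln_bias[i]
    arrays["W1"] = params.W1
    arrays["W2"] = params.W2
    for i, w in enumerate(params.head_weights):
        arrays[f"head_W_{i}"] = w
        arrays[f"head_b_{i}"] = params.head_biases[i]
    meta["n_gcn"] = len(params.gcn_weights)
    meta["n_head"] = len(params.head_weights)
    if scaler is not None:
        arrays["scaler_mean"] = scaler.mean_
        arrays["scaler_std"] = scaler.std_
        meta["scaler_groups"] = list(scaler.group_order)
    if scheme is not None:
        meta["scheme"] = {"mode": scheme.mode, "alpha": scheme.alpha,
                          "weighting": scheme.weighting}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(params, config, scaler, scheme)``.

    ``scaler`` / ``scheme`` are ``None`` when the archive has none.
    """
    from .features import FeatureScaler
    from .graphs import EdgeScheme

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version: {meta.get('format_version')}")
        cfg = meta["config"]
        config = ModelConfig(
            input_dim=cfg["input_dim"], gcn_dims=tuple(cfg["gcn_dims"]),
            attention_heads=cfg["attention_heads"],
            attention_hidden=cfg["attention_hidden"],
            head_dims=tuple(cfg["head_dims"]),
        )
        params = ModelParameters(
            gcn_weights=[data[f"gcn_W_{i}"] for i in range(meta["n_gcn"])],
            ln_gain=[data[f"ln_gain_{i}"] for i in range(meta["n_gcn"])],
            ln_bias=[data[f"ln_bias_{i}"] for i in range(meta["n_gcn"])],
            W1=data["W1"], W2=data["W2"],
            head_weights=[data[f"head_W_{i}"] for i in range(meta["n_head"])],
            head_biases=[data[f"head_b_{i}"] for i in range(meta["n_head"])],
        )
        scaler = None
        if "scaler_mean" in data:
            scaler = FeatureScaler(
                mean_=data["scaler_mean"], std_=data["scaler_std"],
                group_order=tuple(meta.get("scaler_groups", ())),
            )
        scheme = None
        if "scheme" in meta:
            scheme = EdgeScheme(**meta["scheme"])
    return params, config, scaler, scheme
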