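"""The two-branch prediction network.

Sequence branch: for each kernel size ``h`` a bank of 1D filters slides
over the one-hot sequence (valid padding, output length ``k - h + 1`` at
stride 1), followed by batch normalization, a rectifier and global max
pooling; the pooled vectors are concatenated and passed through two
dropout+dense layers down to the embedding width ``d``, giving the
protein representation ``Z`` (one row per protein).

Term branch: a stacked graph convolution over the normalized correlation
matrix ``Â``. Starting from the one-hot term identity ``H⁰ = I``, each
layer computes ``H^{l+1} = f(Â H^l W^l)`` with a rectifier between layers
and a linear final layer, giving the term representation ``H``
(one row per term, width ``d``). With ``gcn_layers=0`` the term matrix is
instead a free learned parameter (the CNN-only ablation).

Fusion: logits ``Ŷ[i, s] = ⟨Z_i, H_s⟩``; sigmoid probabilities; binary
cross-entropy summed over terms and averaged over the proteins of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1dOneHot,
    Dense,
    Dropout,
    GlobalMaxPool,
    ReLU,
    sigmoid,
    softplus,
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Kernel sizes 8/16/24/32 probe short- to long-range sequence context;
    each size contributes ``filters_per_kernel`` feature maps. ``embed_dim``
    is the shared width of the protein and term representations.
    """

    kernel_sizes: tuple = (8, 16, 24, 32)
    filters_per_kernel: int = 128
    stride: int = 1
    seq_len: int = 2000
    alphabet_size: int = 21
    embed_dim: int = 128
    dense_hidden: int = 256
    gcn_layers: int = 2
    dropout_p: float = 0.5
    activation: str = "relu"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if any(h >= self.seq_len for h in self.kernel_sizes):
            raise ValueError("every kernel size must be smaller than seq_len")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be at least 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["kernel_sizes"] = tuple(d.get("kernel_sizes", (8, 16, 24, 32)))
        return cls(**d)


def fuse_predict(H: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Dot-product fusion: logits of shape (proteins, terms)."""
    H = np.asarray(H)
    Z = np.asarray(Z)
    if H.shape[1] != Z.shape[1]:
        raise ValueError(
            f"embedding width mismatch: H has {H.shape[1]}, Z has {Z.shape[1]}"
        )
    return Z @ H.T


def bce_loss(y: np.ndarray, logits: np.ndarray) -> float:
    """Binary cross-entropy from logits, summed over terms and averaged
    over proteins.

    Computed as ``softplus(x) - y·x`` per entry, which is finite for
    arbitrarily large |logits|.
    """
    y = np.asarray(y, dtype=float)
    logits = np.asarray(logits, dtype=float)
    if y.shape != logits.shape:
        raise ValueError(f"shape mismatch: labels {y.shape}, logits {logits.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    n = y.shape[0] if y.ndim > 1 else 1
    return float((softplus(logits) - y * logits).sum() / n)


def bce_loss_grad(y: np.ndarray, logits: np.ndarray) -> np.ndarray:
    """Gradient of :func:`bce_loss` with respect to the logits."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0] if y.ndim > 1 else 1
    return (sigmoid(np.asarray(logits, dtype=float)) - y) / n


class DeepGOANetwork:
    """Joint CNN+GCN network with explicit backward passes.

    Parameters
    ----------
    config
        Architecture settings.
    n_terms
        Number of selected terms ``|T|`` (side of ``Â``).
    rng
        Seeded generator for initialization and dropout; defaults to
        ``default_rng(config.seed)``.
    """

    def __init__(self, config: ModelConfig, n_terms: int,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.n_terms = n_terms
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        dtype = np.dtype(config.dtype).type
        c = config

        self.conv_blocks = []
        for h in c.kernel_sizes:
            block = {
                "conv": Conv1dOneHot(h, c.alphabet_size, c.filters_per_kernel,
                                     rng, stride=c.stride, dtype=dtype),
                "bn": BatchNorm1d(c.filters_per_kernel, dtype=dtype),
                "relu": ReLU(),
                "pool": GlobalMaxPool(),
            }
            self.conv_blocks.append(block)
        concat = c.filters_per_kernel * len(c.kernel_sizes)
        self.drop1 = Dropout(c.dropout_p, rng)
        self.fc1 = Dense(concat, c.dense_hidden, rng, dtype=dtype)
        self.fc_relu = ReLU()
        self.drop2 = Dropout(c.dropout_p, rng)
        self.fc2 = Dense(c.dense_hidden, c.embed_dim, rng, dtype=dtype)

        self.gcn_weights = []
        self.gcn_relus = []
        if c.gcn_layers == 0:
            limit = np.sqrt(6.0 / (n_terms + c.embed_dim))
            self.free_H = rng.uniform(-limit, limit,
                                      size=(n_terms, c.embed_dim)).astype(dtype)
            self.free_H_grad = np.zeros_like(self.free_H)
        else:
            self.free_H = None
            widths = [n_terms] + [c.embed_dim] * c.gcn_layers
            for l in range(c.gcn_layers):
                limit = np.sqrt(6.0 / (widths[l] + widths[l + 1]))
                self.gcn_weights.append(
                    rng.uniform(-limit, limit,
                                size=(widths[l], widths[l + 1])).astype(dtype)
                )
                self.gcn_relus.append(ReLU())
            self.gcn_grads = [np.zeros_like(w) for w in self.gcn_weights]

    # -- parameter access ------------------------------------------------
    def parameters(self) -> list:
        """(name, value, grad) triples for every trainable array."""
        out = []
        for bi, block in enumerate(self.conv_blocks):
            for lname in ("conv", "bn"):
                layer = block[lname]
                for pname, val in layer.params.items():
                    out.append((f"{lname}{bi}.{pname}", val, layer.grads[pname]))
        for lname, layer in (("fc1", self.fc1), ("fc2", self.fc2)):
            for pname, val in layer.params.items():
                out.append((f"{lname}.{pname}", val, layer.grads[pname]))
        if self.free_H is not None:
            out.append(("free_H", self.free_H, self.free_H_grad))
        for li, w in enumerate(self.gcn_weights):
            out.append((f"gcn{li}.W", w, self.gcn_grads[li]))
        return out

    def state_dict(self) -> dict:
        state = {name: val.copy() for name, val, _ in self.parameters()}
        for bi, block in enumerate(self.conv_blocks):
            state[f"bn{bi}.running_mean"] = block["bn"].running_mean.copy()
            state[f"bn{bi}.running_var"] = block["bn"].running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, val, _ in self.parameters():
            val[...] = state[name]
        for bi, block in enumerate(self.conv_blocks):
            block["bn"].running_mean[...] = state[f"bn{bi}.running_mean"]
            block["bn"].running_var[...] = state[f"bn{bi}.running_var"]

    # -- sequence branch -------------------------------------------------
    def cnn_forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """One-hot batch ``(n, seq_len, alphabet)`` → protein matrix ``Z``."""
        if batch.ndim != 3 or batch.shape[2] != self.config.alphabet_size:
            raise ValueError(
                f"expected (n, length, {self.config.alphabet_size}) input, "
                f"got shape {batch.shape}"
            )
        pooled = []
        for block in self.conv_blocks:
            x = block["conv"].forward(batch, train)
            x = block["bn"].forward(x, train)
            x = block["relu"].forward(x, train)
            pooled.append(block["pool"].forward(x, train))
        x = np.concatenate(pooled, axis=1)
        self._split = [p.shape[1] for p in pooled]
        x = self.drop1.forward(x, train)
        x = self.fc1.forward(x, train)
        x = self.fc_relu.forward(x, train)
        x = self.drop2.forward(x, train)
        return self.fc2.forward(x, train)

    def cnn_backward(self, gZ: np.ndarray) -> None:
        g = self.fc2.backward(gZ)
        g = self.drop2.backward(g)
        g = self.fc_relu.backward(g)
        g = self.fc1.backward(g)
        g = self.drop1.backward(g)
        offset = 0
        for block, width in zip(self.conv_blocks, self._split):
            gp = g[:, offset:offset + width]
            offset += width
            gx = block["pool"].backward(gp)
            gx = block["relu"].backward(gx)
            gx = block["bn"].backward(gx)
            block["conv"].backward(gx)

    # -- term branch -----------------------------------------------------
    def gcn_forward(self, a_hat: np.ndarray | None, train: bool = False) -> np.ndarray:
        """Normalized correlation matrix → term matrix ``H`` (|T| × d)."""
        if self.free_H is not None:
            return self.free_H
        if a_hat is None:
            raise ValueError("gcn_forward needs the normalized correlation matrix")
        if a_hat.shape != (self.n_terms, self.n_terms):
            raise ValueError(
                f"correlation matrix shape {a_hat.shape} does not match "
                f"{self.n_terms} terms"
            )
        a_hat = a_hat.astype(self.gcn_weights[0].dtype, copy=False)
        self._gcn_inputs = []
        h = np.eye(self.n_terms, dtype=a_hat.dtype)
        last = len(self.gcn_weights) - 1
        for l, w in enumerate(self.gcn_weights):
            ah = a_hat @ h
            self._gcn_inputs.append(ah)
            h = ah @ w
            if l != last:
                h = self.gcn_relus[l].forward(h, train)
        self._a_hat = a_hat
        return h

    def gcn_backward(self, gH: np.ndarray) -> None:
        if self.free_H is not None:
            self.free_H_grad[...] = gH
            return
        g = gH
        last = len(self.gcn_weights) - 1
        for l in range(last, -1, -1):
            if l != last:
                g = self.gcn_relus[l].backward(g)
            self.gcn_grads[l][...] = self._gcn_inputs[l].T @ g
            if l > 0:
                g = self._a_hat.T @ (g @ self.gcn_weights[l].T)

    # -- joint pass ------------------------------------------------------
    def forward(self, batch: np.ndarray, a_hat: np.ndarray | None,
                train: bool = False) -> tuple:
        """Returns ``(logits, Z, H)`` for a batch of encoded sequences."""
        Z = self.cnn_forward(batch, train)
        H = self.gcn_forward(a_hat, train)
        return fuse_predict(H, Z), Z, H

    def backward(self, glogits: np.ndarray, Z: np.ndarray, H: np.ndarray) -> None:
        self.cnn_backward(glogits @ H)
        self.gcn_backward(glogits.T @ Z)

    def predict_proba(self, batch: np.ndarray, a_hat: np.ndarray | None) -> np.ndarray:
        """Deterministic sigmoid probabilities in evaluation mode."""
        logits, _, _ = self.forward(batch, a_hat, train=False)
        return sigmoid(logits)
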