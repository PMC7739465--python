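"""Model/Results interface for training the joint CNN+GCN predictor.

:class:`DeepGOAModel` holds the data (label matrix, encoded sequences,
ontology) and the architecture configuration; :meth:`DeepGOAModel.fit`
runs the seeded 80/20 protein split, derives the term-correlation matrix
from the training partition, optimizes the network end-to-end with Adam,
and returns a :class:`DeepGOAResults` carrying the fitted parameters,
the per-epoch history and the evaluation panel.

    >>> model = DeepGOAModel(labels, encodings, graph=graph)
    >>> res = model.fit(TrainConfig(max_epochs=20, seed=1))
    >>> print(res.summary())
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import metrics
from .annotations import LabelMatrix
from .nn import Adam, DeepGOANetwork, ModelConfig, bce_loss, bce_loss_grad, sigmoid
from .ontology import (
    OntologyGraph,
    correlation_matrix,
    information_content,
    normalize_adjacency,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings: 80/20 protein split, Adam at 1e-3, early
    stopping on validation Fmax."""

    train_fraction: float = 0.8
    batch_size: int = 32
    max_epochs: int = 50
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("batch_size must be positive, max_epochs nonnegative")


def split_proteins(ids, config: TrainConfig):
    """Seeded shuffle; first ``⌊train_fraction·n⌋`` ids train, rest validate."""
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins to split")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(config.train_fraction * len(ids)))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:]]
    return train, val


def naive_baseline(train_labels: np.ndarray, n_proteins: int) -> np.ndarray:
    """Frequency baseline: every protein gets each term's training frequency.

    The same score row — annotated-protein count over training-set size —
    is assigned to all queried proteins.
    """
    train_labels = np.asarray(train_labels)
    if train_labels.size == 0 or train_labels.shape[0] == 0:
        raise ValueError("naive baseline needs a nonempty training set")
    freq = train_labels.mean(axis=0)
    return np.tile(freq, (n_proteins, 1))


class DeepGOAModel:
    """Joint sequence/ontology predictor over one sub-ontology.

    Parameters
    ----------
    labels
        TPR-closed binary :class:`~gogcn.annotations.LabelMatrix`.
    encodings
        One-hot sequences, shape ``(n_proteins, seq_len, 21)``, aligned
        with ``labels.proteins``.
    graph
        Parsed ontology; used to compute information content and, from
        the training partition's annotation counts, the correlation
        matrix the GCN consumes. Optional when ``a_hat`` is given or the
        CNN-only ablation (``gcn_layers=0``) is requested.
    a_hat
        Precomputed normalized correlation matrix (overrides ``graph``).
    config
        Architecture settings; ``seq_len`` is taken from the encodings.
    """

    def __init__(self, labels: LabelMatrix, encodings: np.ndarray,
                 graph: OntologyGraph | None = None,
                 a_hat: np.ndarray | None = None,
                 ic: np.ndarray | None = None,
                 config: ModelConfig | None = None):
        encodings = np.asarray(encodings, dtype=np.float32)
        if encodings.shape[0] != len(labels.proteins):
            raise ValueError(
                f"{encodings.shape[0]} encodings for {len(labels.proteins)} proteins"
            )
        if config is None:
            config = ModelConfig(seq_len=encodings.shape[1])
        elif config.seq_len != encodings.shape[1]:
            raise ValueError(
                f"config.seq_len={config.seq_len} but encodings have length "
                f"{encodings.shape[1]}"
            )
        if graph is None and a_hat is None and config.gcn_layers > 0:
            raise ValueError(
                "graph convolution needs an ontology graph or a precomputed "
                "correlation matrix; pass gcn_layers=0 for the CNN-only ablation"
            )
        self.labels = labels
        self.encodings = encodings
        self.graph = graph
        self.config = config
        self._a_hat_fixed = None if a_hat is None else np.asarray(a_hat, dtype=float)
        if ic is not None:
            self.ic = np.asarray(ic, dtype=float)
        elif graph is not None:
            self.ic = information_content(graph, labels.index)
        else:
            self.ic = np.ones(len(labels.index), dtype=float)

    @classmethod
    def from_dataset(cls, dataset, config: ModelConfig | None = None):
        """Build from a :class:`~gogcn.cli.DatasetBundle`-like object."""
        return cls(dataset.labels, dataset.encodings, graph=dataset.graph,
                   ic=dataset.ic, config=config)

    # -----------------------------------------------------------------
    def _correlation_from(self, train_rows: np.ndarray) -> np.ndarray:
        """Â from training-partition annotation counts (Laplace-free)."""
        if self._a_hat_fixed is not None:
            return self._a_hat_fixed
        if self.config.gcn_layers == 0:
            return None
        counts_arr = np.asarray(self.labels.values)[train_rows].sum(axis=0)
        # a selected term can be absent from the training partition; a unit
        # pseudo-count keeps the frequency ratio defined
        counts = {
            t: int(max(counts_arr[i], 1)) for i, t in enumerate(self.labels.index)
        }
        ic = self.ic
        if (ic <= 0).any():
            # Eq-style IC can reach zero (or below) on covering terms; the
            # sibling-share denominator needs positive mass, so shift for A
            ic = ic - min(ic.min(), 0.0) + 1e-6
        A = correlation_matrix(self.graph, self.labels.index, counts, ic)
        return normalize_adjacency(A)

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False) -> "DeepGOAResults":
        """Train end-to-end; returns the results object.

        The protein split, parameter initialization, batch order and
        dropout masks all derive from ``train_config.seed``, so two runs
        with the same seed produce identical histories.
        """
        tc = train_config or TrainConfig()
        train_ids, val_ids = split_proteins(self.labels.proteins, tc)
        pos = {p: i for i, p in enumerate(self.labels.proteins)}
        train_rows = np.array([pos[p] for p in train_ids], dtype=int)
        val_rows = np.array([pos[p] for p in val_ids], dtype=int)

        a_hat = self._correlation_from(train_rows)
        rng = np.random.default_rng(tc.seed)
        net = DeepGOANetwork(self.config, len(self.labels.index), rng=rng)
        optimizer = Adam(lr=tc.learning_rate)

        X = self.encodings
        Y = np.asarray(self.labels.values, dtype=np.float32)
        history = []
        best_state = net.state_dict()
        best_val_fmax, best_epoch, stale = -np.inf, -1, 0

        for epoch in range(tc.max_epochs):
            order = rng.permutation(len(train_rows))
            losses = []
            for start in range(0, len(order), tc.batch_size):
                rows = train_rows[order[start:start + tc.batch_size]]
                logits, Z, H = net.forward(X[rows], a_hat, train=True)
                y = Y[rows]
                loss = bce_loss(y, logits)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={loss}"
                    )
                net.backward(bce_loss_grad(y, logits).astype(logits.dtype), Z, H)
                optimizer.step(net.parameters())
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if len(val_rows):
                probs = _predict_in_batches(net, X[val_rows], a_hat)
                val_fmax, _ = metrics.fmax(Y[val_rows], probs)
                record["val_fmax"] = val_fmax
                if val_fmax > best_val_fmax:
                    best_val_fmax, best_epoch, stale = val_fmax, epoch, 0
                    best_state = net.state_dict()
                else:
                    stale += 1
            history.append(record)
            if verbose:
                logger.info("epoch %d: %s", epoch, record)
            if tc.early_stop_patience and stale >= tc.early_stop_patience:
                break

        # restoring the best-validation checkpoint is part of early stopping;
        # with patience disabled the final weights are kept
        if tc.early_stop_patience and len(val_rows) and best_epoch >= 0:
            net.load_state_dict(best_state)
        return DeepGOAResults(
            model=self,
            network=net,
            a_hat=a_hat,
            train_config=tc,
            train_ids=train_ids,
            val_ids=val_ids,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
        )


def _predict_in_batches(net, X, a_hat, batch_size: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch_size):
        out.append(net.predict_proba(X[start:start + batch_size], a_hat))
    return np.vstack(out)


class DeepGOAResults:
    """Fitted network plus split bookkeeping, history and evaluation."""

    def __init__(self, model: DeepGOAModel, network: DeepGOANetwork,
                 a_hat, train_config: TrainConfig, train_ids, val_ids,
                 history: pd.DataFrame, best_epoch: int):
        self.model = model
        self.network = network
        self.a_hat = a_hat
        self.train_config = train_config
        self.train_ids = list(train_ids)
        self.val_ids = list(val_ids)
        self.history = history
        self.best_epoch = best_epoch

    # -- prediction ----------------------------------------------------
    def predict(self, encodings: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities, shape ``(n, |T|)``, deterministic."""
        encodings = np.asarray(encodings, dtype=np.float32)
        return _predict_in_batches(self.network, encodings, self.a_hat)

    def _rows(self, ids):
        pos = {p: i for i, p in enumerate(self.model.labels.proteins)}
        return np.array([pos[p] for p in ids], dtype=int)

    def predict_split(self, which: str = "val") -> tuple:
        ids = self.val_ids if which == "val" else self.train_ids
        rows = self._rows(ids)
        truth = np.asarray(self.model.labels.values)[rows]
        return truth, self.predict(self.model.encodings[rows])

    def evaluate(self, which: str = "val",
                 cafa_recall: bool = False) -> metrics.EvalReport:
        """Metric panel (AUC/AUPRC/PR50/Fmax/Smin) on one partition."""
        truth, probs = self.predict_split(which)
        return metrics.evaluate(truth, probs, self.model.ic,
                                cafa_recall=cafa_recall)

    def naive_scores(self, n_proteins: int | None = None) -> np.ndarray:
        """Frequency-baseline scores from this fit's training partition."""
        rows = self._rows(self.train_ids)
        n = n_proteins if n_proteins is not None else len(self.val_ids)
        return naive_baseline(np.asarray(self.model.labels.values)[rows], n)

    def summary(self) -> str:
        lines = [
            "Joint CNN+GCN function predictor",
            "================================",
            f"proteins: {len(self.model.labels.proteins)} "
            f"({len(self.train_ids)} train / {len(self.val_ids)} validation)",
            f"selected terms: {len(self.model.labels.index)}",
            f"embedding width d: {self.model.config.embed_dim}",
            f"kernel sizes: {list(self.model.config.kernel_sizes)} x "
            f"{self.model.config.filters_per_kernel} filters",
            f"gcn layers: {self.model.config.gcn_layers}",
            f"epochs run: {len(self.history)} (best: {self.best_epoch})",
        ]
        if len(self.history):
            lines.append(f"final train loss: {self.history['train_loss'].iloc[-1]:.4f}")
        if "val_fmax" in self.history:
            lines.append(f"best validation Fmax: {self.history['val_fmax'].max():.4f}")
            report = self.evaluate("val")
            lines.append("")
            lines.append(report.summary())
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights + config + term manifest (npz + json header)."""
        state = self.network.state_dict()
        meta = {
            "model_config": self.model.config.to_dict(),
            "train_config": asdict(self.train_config),
            "terms": list(self.model.labels.index.terms),
            "namespace": self.model.labels.index.namespace,
            "ic": list(map(float, self.model.ic)),
        }
        arrays = {f"param::{k}": v for k, v in state.items()}
        if self.a_hat is not None:
            arrays["a_hat"] = self.a_hat
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load_checkpoint(path):
        """Load ``(network, a_hat, model_config, terms, namespace, ic)``."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = ModelConfig.from_dict(meta["model_config"])
            net = DeepGOANetwork(config, len(meta["terms"]))
            state = {
                k[len("param::"):]: data[k]
                for k in data.files if k.startswith("param::")
            }
            net.load_state_dict(state)
            a_hat = data["a_hat"] if "a_hat" in data.files else None
        return net, a_hat, config, meta["terms"], meta["namespace"], np.asarray(
            meta["ic"])
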