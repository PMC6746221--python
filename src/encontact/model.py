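"""Twin-CNN + attention-BLSTM model for enhancer-enhancer contact prediction.

Each enhancer of a pair is read by its own convolution tower (full-width kernels
over the one-hot matrix, ReLU, non-overlapping max-pooling). The two pooled
feature sequences are concatenated along the time axis — so the recurrent layer
traverses both enhancers — normalized, regularized with dropout, passed through
a bidirectional LSTM, pooled with softmax attention, and fed to a ReLU dense
layer ending in a single logistic output: the probability that the two enhancers
are in contact. Training minimizes binary cross-entropy with Adam and early
stopping on a validation carve-out.

The two towers have independent (untied) weights, so the model is not symmetric
in the pair order; an optional swap augmentation adds each training pair in both
orientations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nn

#: Probability threshold above which a pair is called positive (strict ">").
CALL_THRESHOLD = 0.5


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters.

    The published architecture leaves the layer sizes unspecified, so these
    defaults are this package's configuration; every field can be overridden.
    """

    n_kernels: int = 64
    kernel_len: int = 8
    pool_window: int = 10
    blstm_units: int = 50
    dense_units: int = 128
    dropout_rate: float = 0.5
    batchnorm: bool = True
    merge_mode: str = "time"  # "time" (BLSTM traverses both enhancers) or "channel"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    validation_fraction: float = 0.1
    swap_augment: bool = False
    conv_l1: float = 0.0  # L1 penalty on convolution weights (sparser kernels)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_len < 2:
            raise ValueError("kernel_len must be >= 2")
        if self.pool_window < 1:
            raise ValueError("pool_window must be >= 1")
        for name in ("n_kernels", "blstm_units", "dense_units", "batch_size",
                     "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.merge_mode not in ("time", "channel"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")


@dataclass(frozen=True)
class PredictionRecord:
    """A scored enhancer pair; ``call`` is positive iff probability > threshold."""

    e1: str
    e2: str
    probability: float
    call: bool
    source: str | None = None


def _pair_fields(pair) -> tuple[str, str, int | None]:
    if hasattr(pair, "e1"):
        return pair.e1, pair.e2, getattr(pair, "label", None)
    e1, e2 = pair[0], pair[1]
    label = pair[2] if len(pair) > 2 else None
    return e1, e2, label


class EnContactModel:
    """The assembled network; build with :func:`build_model` or the constructor."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        K, M, W = spec.n_kernels, spec.kernel_len, spec.pool_window
        self.tower_a = nn.ConvTower(K, M, rng, name="tower_a")
        self.pool_a = nn.MaxPoolLayer(W)
        self.tower_b = nn.ConvTower(K, M, rng, name="tower_b")
        self.pool_b = nn.MaxPoolLayer(W)
        merged_channels = K if spec.merge_mode == "time" else 2 * K
        self.bn = nn.BatchNorm(merged_channels) if spec.batchnorm else None
        self.drop1 = nn.Dropout(spec.dropout_rate, rng)
        self.blstm = nn.BiLSTM(merged_channels, spec.blstm_units, rng)
        self.attention = nn.AttentionLayer(2 * spec.blstm_units, rng)
        self.dense = nn.Dense(2 * spec.blstm_units, spec.dense_units, rng,
                              activation="relu", name="dense")
        self.drop2 = nn.Dropout(spec.dropout_rate, rng)
        self.out = nn.Dense(spec.dense_units, 1, rng, name="out", zero_init=True)
        self._rng = rng
        self.history: list[dict] = []

    # -- plumbing ----------------------------------------------------------

    def params(self) -> list[nn.Param]:
        layers = [self.tower_a, self.tower_b, self.bn, self.blstm,
                  self.attention, self.dense, self.out]
        return [p for layer in layers if layer is not None for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    @property
    def kernels(self) -> np.ndarray:
        """Convolution kernels of both towers, shape (2*n_kernels, M, 4)."""
        return np.concatenate([self.tower_a.kernels, self.tower_b.kernels])

    # -- forward / backward ------------------------------------------------

    def forward(self, X1: np.ndarray, X2: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.pool_a.forward(self.tower_a.forward(X1, train), train)
        b = self.pool_b.forward(self.tower_b.forward(X2, train), train)
        axis = 1 if self.spec.merge_mode == "time" else 2
        self._split = a.shape[axis]
        h = np.concatenate([a, b], axis=axis)
        if self.bn is not None:
            h = self.bn.forward(h, train)
        h = self.drop1.forward(h, train)
        h = self.blstm.forward(h, train)
        theta = self.attention.forward(h, train)
        h = self.dense.forward(theta, train)
        h = self.drop2.forward(h, train)
        return self.out.forward(h, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out.backward(dlogits[:, None])
        d = self.drop2.backward(d)
        d = self.dense.backward(d)
        d = self.attention.backward(d)
        d = self.blstm.backward(d)
        d = self.drop1.backward(d)
        if self.bn is not None:
            d = self.bn.backward(d)
        axis = 1 if self.spec.merge_mode == "time" else 2
        da, db = np.split(d, [self._split], axis=axis)
        self.tower_a.backward(self.pool_a.backward(da))
        self.tower_b.backward(self.pool_b.backward(db))

    def predict_proba(self, X1: np.ndarray, X2: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        probs = []
        for lo in range(0, X1.shape[0], batch_size):
            logits = self.forward(X1[lo : lo + batch_size], X2[lo : lo + batch_size])
            probs.append(nn.sigmoid(logits))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- training ----------------------------------------------------------

    def fit(self, pairs: Sequence, sequences: Mapping[str, np.ndarray],
            verbose: bool = False) -> "EnContactModel":
        """Train on labeled pairs; early-stops on a stratified validation carve-out."""
        spec = self.spec
        triples = [_pair_fields(p) for p in pairs]
        labels = np.array([t[2] for t in triples], dtype=np.float64)
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain both labels")
        if spec.swap_augment:
            triples = triples + [(e2, e1, y) for e1, e2, y in triples]
            labels = np.concatenate([labels, labels])

        X1 = np.stack([sequences[t[0]] for t in triples])
        X2 = np.stack([sequences[t[1]] for t in triples])

        # stratified validation carve-out
        rng = self._rng
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        rng.shuffle(pos)
        rng.shuffle(neg)
        n_val_pos = max(1, int(round(spec.validation_fraction * pos.size)))
        n_val_neg = max(1, int(round(spec.validation_fraction * neg.size)))
        val_idx = np.concatenate([pos[:n_val_pos], neg[:n_val_neg]])
        tr_idx = np.concatenate([pos[n_val_pos:], neg[n_val_neg:]])
        Xv1, Xv2, yv = X1[val_idx], X2[val_idx], labels[val_idx]
        Xt1, Xt2, yt = X1[tr_idx], X2[tr_idx], labels[tr_idx]

        optimizer = nn.Adam(self.params(), lr=spec.learning_rate)
        eps = 1e-12

        def val_loss_now() -> float:
            p = self.predict_proba(Xv1, Xv2)
            return float(-np.mean(
                yv * np.log(p + eps) + (1 - yv) * np.log(1 - p + eps)))

        # the untrained state is an early-stopping candidate: training that
        # never beats the uninformative predictor on validation is discarded
        best_val = val_loss_now()
        best_state = self.state_dict()
        stale = 0
        for epoch in range(spec.max_epochs):
            order = rng.permutation(yt.size)
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, yt.size, spec.batch_size):
                idx = order[lo : lo + spec.batch_size]
                logits = self.forward(Xt1[idx], Xt2[idx], train=True)
                loss, dlogits = nn.binary_cross_entropy_from_logits(logits, yt[idx])
                optimizer.zero_grad()
                self.backward(dlogits)
                if spec.conv_l1 > 0:
                    for tower in (self.tower_a, self.tower_b):
                        tower.W.grad += spec.conv_l1 * np.sign(tower.W.value)
                optimizer.step()
                epoch_loss += loss
                n_batches += 1
            val_loss = val_loss_now()
            self.history.append(
                {"epoch": epoch, "train_loss": epoch_loss / n_batches,
                 "val_loss": val_loss})
            if verbose:
                print(f"epoch {epoch}: train {epoch_loss / n_batches:.4f} "
                      f"val {val_loss:.4f}")
            if val_loss < best_val - 1e-5:
                best_val = val_loss
                best_state = self.state_dict()
                stale = 0
            else:
                stale += 1
                if stale > spec.patience:
                    break
        self.load_state_dict(best_state)
        return self

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        if self.bn is not None:
            state["bn.running_mean"] = self.bn.running_mean.copy()
            state["bn.running_var"] = self.bn.running_var.copy()
        return state

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        if self.bn is not None:
            self.bn.running_mean[...] = state["bn.running_mean"]
            self.bn.running_var[...] = state["bn.running_var"]

    def save(self, path: str) -> None:
        """Single-file archive holding the spec as JSON plus all weight arrays."""
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __spec__=np.frombuffer(
            json.dumps(asdict(self.spec)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "EnContactModel":
        with np.load(path) as archive:
            spec = ModelSpec(**json.loads(bytes(archive["__spec__"]).decode()))
            model = cls(spec)
            state = {k.replace("__", "."): archive[k]
                     for k in archive.files if k != "__spec__"}
        model.load_state_dict(state)
        return model


def build_model(spec: ModelSpec) -> EnContactModel:
    """Construct an untrained model from an architecture spec."""
    return EnContactModel(spec)


def train(model: EnContactModel, train_pairs: Sequence,
          sequences: Mapping[str, np.ndarray], verbose: bool = False) -> EnContactModel:
    """Fit ``model`` on labeled pairs (binary cross-entropy, Adam, early stopping)."""
    return model.fit(train_pairs, sequences, verbose=verbose)


def predict_pairs(model: EnContactModel, pairs: Sequence,
                  sequences: Mapping[str, np.ndarray],
                  threshold: float = CALL_THRESHOLD,
                  source: str | None = None) -> list[PredictionRecord]:
    """Score pairs and call positives where probability strictly exceeds the threshold."""
    records: list[PredictionRecord] = []
    if not pairs:
        return records
    ids = [_pair_fields(p)[:2] for p in pairs]
    for e1, e2 in ids:
        for eid in (e1, e2):
            if eid not in sequences:
                raise KeyError(f"no sequence for enhancer {eid!r}")
    X1 = np.stack([sequences[e1] for e1, _ in ids])
    X2 = np.stack([sequences[e2] for _, e2 in ids])
    probs = model.predict_proba(X1, X2)
    for (e1, e2), p in zip(ids, probs):
        records.append(PredictionRecord(e1=e1, e2=e2, probability=float(p),
                                        call=bool(p > threshold), source=source))
    return records


def evaluate(scores: Iterable[float] | Iterable[PredictionRecord],
             labels: Iterable[int]) -> dict[str, float]:
    """AUROC and AUPRC for scored pairs; both classes must be present."""
    scores = [s.probability if isinstance(s, PredictionRecord) else float(s)
              for s in scores]
    y = np.asarray(list(labels), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires both positive and negative labels")
    return {
        "auroc": float(roc_auc_score(y, scores)),
        "auprc": float(average_precision_score(y, scores)),
    }


def fine_map_mvm(model: EnContactModel, candidate_sets: Sequence,
                 sequences: Mapping[str, np.ndarray],
                 threshold: float = CALL_THRESHOLD) -> dict[str, list[PredictionRecord]]:
    """Score every candidate pair of each ambiguous region-level interaction.

    Returns all scored candidates keyed by the source interaction id; positive
    calls (probability strictly above the threshold) carry provenance to their
    region. A region may yield zero positives.
    """
    results: dict[str, list[PredictionRecord]] = {}
    for cs in candidate_sets:
        source = cs.source if hasattr(cs, "source") else cs[0]
        candidates = cs.candidates if hasattr(cs, "candidates") else cs[1]
        results[source] = predict_pairs(model, candidates, sequences,
                                        threshold=threshold, source=source)
    return results


def positive_calls(results: Mapping[str, list[PredictionRecord]]
                   ) -> list[PredictionRecord]:
    """Flatten fine-mapping output to the positive predictions only."""
    return [r for records in results.values() for r in records if r.call]
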