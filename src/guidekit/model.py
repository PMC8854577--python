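"""Guide-activity networks: autoencoder pre-training and CS prediction.

Three cooperating networks:

1. a convolutional autoencoder (CAE) trained to reconstruct one-hot genome
   k-mers, whose encoder learns the genomic background distribution;
2. a predictor sharing the encoder architecture, followed by a flatten layer
   and up to three fully connected layers (fc8: 80, fc9: 40, fc10: 40), that
   regresses a guide's cutting score from its sequence context;
3. an optional occupancy branch that expands the scalar [0, 1] nucleosome
   occupancy into a vector matching the last sequence layer and merges it by
   element-wise multiplication.

Encoder stack (input 4 x n): conv(20 filters) -> max-pool(2) -> batch-norm ->
conv(40 filters) -> avg-pool(2) -> batch-norm, all ReLU, Glorot-uniform init,
L2 1e-4 on weights; the flattened feature is ⌊n/4⌋ x 40 wide (280 for n=28,
320 for n=32).  The final Cas12a configuration is encoder->fc8->fc9->output;
the final Cas9 configuration is encoder->fc8->(x occupancy branch)->output.

Estimators follow scikit-learn conventions (``fit``/``predict``/
``get_params``; fitted attributes end in an underscore) and compose with
sklearn model selection.  For occupancy-aware models, X carries the
flattened one-hot window in the first 4n columns and the occupancy scalar in
the last column.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import _nn
from ._nn import (Conv1D, ReLU, MaxPool1D, AvgPool1D, BatchNorm1D, UpSample1D,
                  Flatten, Dense, Sequential, Adam,
                  mse_loss, bce_with_logits_loss, sigmoid)
from .genome import one_hot_batch

FC_WIDTHS = {"fc8": 80, "fc9": 40, "fc10": 40}

#: ablation variants: which fully connected layers sit between flatten and output
VARIANT_FCS = {
    "encoder_only": [],
    "fc8": [80],
    "fc8+fc9": [80, 40],
    "fc8+fc9+fc10": [80, 40, 40],
}

#: architectures selected by the ablation analysis
FINAL_VARIANTS = {
    "cas12a-final": dict(variant="fc8+fc9", use_occupancy=False, n=32),
    "cas9-final": dict(variant="fc8", use_occupancy=True, n=28),
}

ACTIVE_CS_THRESHOLDS = {"cas12a": 1.67, "cas9": 4.91}


@dataclass
class ModelSpec:
    """Declarative description of a predictor configuration."""

    nuclease: str = "cas12a"
    n: int = 32
    variant: str = "fc8+fc9"
    use_occupancy: bool = False
    mode: str = "regression"  # or "classification"
    kernel: int = 5
    l2: float = 1e-4

    def __post_init__(self):
        if self.variant not in VARIANT_FCS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANT_FCS)}")


@dataclass
class TrainConfig:
    cae_epochs: int = 200
    cae_batch_size: int = 64
    epochs: int = 150
    patience: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    split: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than max epochs")


def encoder_flat_dim(n: int) -> int:
    """Flattened encoder output width: ⌊n/4⌋ x 40 (two pooling stages of 2)."""
    return (n // 4) * 40


def _encoder_stack(kernel: int, rng) -> Sequential:
    return Sequential([
        Conv1D(4, 20, kernel, rng), ReLU(), MaxPool1D(2), BatchNorm1D(20),
        Conv1D(20, 40, kernel, rng), ReLU(), AvgPool1D(2), BatchNorm1D(40),
    ])


def _decoder_stack(kernel: int, rng) -> Sequential:
    # mirrors the encoder with upsampling in place of pooling; final conv
    # maps back to 4 channels (logits; sigmoid applied by the loss/reconstruct)
    return Sequential([
        Conv1D(40, 40, kernel, rng), ReLU(), UpSample1D(2), BatchNorm1D(40),
        Conv1D(40, 20, kernel, rng), ReLU(), UpSample1D(2), BatchNorm1D(20),
        Conv1D(20, 4, kernel, rng),
    ])


def build_encoder(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Fresh encoder stack for a spec (Glorot-initialized)."""
    return _encoder_stack(spec.kernel, np.random.default_rng(seed))


def occupancy_branch(width: int, rng=None) -> list:
    """Layers expanding a scalar occupancy into a ``width``-sized vector."""
    return [Dense(1, width, rng or np.random.default_rng()), ReLU()]


class CSNetwork:
    """Encoder + FC head + optional multiplicative occupancy branch."""

    def __init__(self, n: int, fcs: list[int], use_occupancy: bool,
                 kernel: int, rng):
        self.n = n
        self.encoder = _encoder_stack(kernel, rng)
        self.flatten = Flatten()
        d = encoder_flat_dim(n)
        self.head: list = []
        w = d
        for width in fcs:
            self.head += [Dense(w, width, rng), ReLU()]
            w = width
        self.merge_width = w
        self.occ_branch = occupancy_branch(w, rng) if use_occupancy else None
        self.out = Dense(w, 1, rng)
        self.use_occupancy = use_occupancy

    # -- forward / backward -------------------------------------------------
    def forward(self, x_seq, occ=None, train=True, freeze_encoder=False):
        h = self.encoder.forward(x_seq, train=train and not freeze_encoder)
        z = self.flatten.forward(h)
        for layer in self.head:
            z = layer.forward(z, train=train)
        if self.use_occupancy:
            if occ is None:
                raise ValueError("model requires an occupancy input")
            o = np.asarray(occ, dtype=float).reshape(-1, 1)
            for layer in self.occ_branch:
                o = layer.forward(o, train=train)
            self._z_seq, self._o = z, o
            z = z * o
        return self.out.forward(z, train=train)

    def backward(self, dout, freeze_encoder=False):
        dz = self.out.backward(dout)
        if self.use_occupancy:
            dm = dz
            dz = dm * self._o
            do = dm * self._z_seq
            for layer in reversed(self.occ_branch):
                do = layer.backward(do)
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        dh = self.flatten.backward(dz)
        if not freeze_encoder:
            self.encoder.backward(dh)

    def trainable_layers(self, freeze_encoder=False):
        layers = list(self.head) + [self.out]
        if self.use_occupancy:
            layers += self.occ_branch
        if not freeze_encoder:
            layers = self.encoder.layers + layers
        return layers

    # -- weights ------------------------------------------------------------
    def all_parts(self):
        parts = [("encoder", self.encoder.layers), ("head", self.head),
                 ("out", [self.out])]
        if self.use_occupancy:
            parts.append(("occ", self.occ_branch))
        return parts

    def get_weights(self):
        return {name: Sequential(layers).get_weights()
                for name, layers in self.all_parts()}

    def set_weights(self, weights):
        for name, layers in self.all_parts():
            Sequential(layers).set_weights(weights[name])


def _as_seq_array(X, n: int) -> np.ndarray:
    """Accept (N, 4, n) one-hot stacks, (N, 4n) flat rows, or sequences."""
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], str):
        X = one_hot_batch(X)
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 4 * n:
            raise ValueError(f"expected {4 * n} columns for n={n}, "
                             f"got {X.shape[1]}")
        X = X.reshape(-1, 4, n)
    if X.ndim != 3 or X.shape[1] != 4 or X.shape[2] != n:
        raise ValueError(f"expected (N, 4, {n}) one-hot input, got {X.shape}")
    return X


def _split_X(X, n: int, use_occupancy: bool):
    """Split a design matrix into (one-hot seq array, occupancy vector)."""
    if isinstance(X, tuple) and len(X) == 2:
        seq, occ = X
        return _as_seq_array(seq, n), np.asarray(occ, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if use_occupancy:
        if X.ndim != 2 or X.shape[1] != 4 * n + 1:
            raise ValueError(f"occupancy models expect (N, {4 * n + 1}) input "
                             "(flat one-hot + occupancy column)")
        return X[:, :-1].reshape(-1, 4, n), X[:, -1]
    return _as_seq_array(X, n), None


def pack_X(windows, occupancy=None) -> np.ndarray:
    """Build the 2-D design matrix the estimators consume: flattened one-hot
    windows, with the occupancy scalar appended as a last column if given."""
    seq = one_hot_batch(windows) if windows and isinstance(windows[0], str) \
        else np.asarray(windows, dtype=float)
    if seq.ndim == 3:
        seq = seq.reshape(seq.shape[0], -1)
    if occupancy is None:
        return seq
    occ = np.asarray(occupancy, dtype=float).reshape(-1, 1)
    return np.hstack([seq, occ])


# ---------------------------------------------------------------------------
# estimators

class KmerAutoencoder(TransformerMixin, BaseEstimator):
    """Convolutional autoencoder over one-hot genome k-mers.

    ``fit`` minimizes binary cross-entropy between the input one-hot matrix
    and the sigmoid decoder output (Adam, default lr 1e-3, batch 64, 200
    epochs, no early stopping).  ``transform`` returns the flattened encoder
    features; ``encoder_weights_`` seeds a :class:`GuideActivityRegressor`.
    """

    def __init__(self, n=28, kernel=5, epochs=200, batch_size=64,
                 learning_rate=1e-3, l2=1e-4, seed=0, verbose=0):
        self.n = n
        self.kernel = kernel
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.seed = seed
        self.verbose = verbose

    def fit(self, X, y=None):
        if self.n % 4 != 0:
            raise ValueError("autoencoder input length must be divisible by 4 "
                             "(two pooling/upsampling stages of 2)")
        X = _as_seq_array(X, self.n)
        if len(X) == 0:
            raise ValueError("empty k-mer set")
        rng = np.random.default_rng(self.seed)
        self.encoder_ = _encoder_stack(self.kernel, rng)
        self.decoder_ = _decoder_stack(self.kernel, rng)
        layers = self.encoder_.layers + self.decoder_.layers
        opt = Adam(layers, lr=self.learning_rate, l2=self.l2)
        self.loss_history_ = []
        idx = np.arange(len(X))
        for epoch in range(self.epochs):
            rng.shuffle(idx)
            total = 0.0
            for lo in range(0, len(idx), self.batch_size):
                batch = X[idx[lo:lo + self.batch_size]]
                logits = self.decoder_.forward(
                    self.encoder_.forward(batch, train=True), train=True)
                loss, grad = bce_with_logits_loss(logits, batch)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite CAE loss at epoch {epoch}")
                self.encoder_.backward(self.decoder_.backward(grad))
                opt.step()
                total += loss * len(batch)
            self.loss_history_.append(total / len(X))
            if self.verbose:
                print(f"[cae] epoch {epoch + 1}/{self.epochs} "
                      f"loss {self.loss_history_[-1]:.5f}")
        self.encoder_weights_ = self.encoder_.get_weights()
        return self

    def transform(self, X):
        X = _as_seq_array(X, self.n)
        h = self.encoder_.forward(X, train=False)
        return h.reshape(h.shape[0], -1)

    def reconstruct(self, X):
        """Per-base reconstruction probabilities (N, 4, n)."""
        X = _as_seq_array(X, self.n)
        logits = self.decoder_.forward(self.encoder_.forward(X, train=False),
                                       train=False)
        return sigmoid(logits)

    def reconstruction_loss(self, X):
        X = _as_seq_array(X, self.n)
        logits = self.decoder_.forward(self.encoder_.forward(X, train=False),
                                       train=False)
        loss, _ = bce_with_logits_loss(logits, X)
        return loss


class GuideActivityRegressor(RegressorMixin, BaseEstimator):
    """Cutting-score predictor: encoder + FC head (+ occupancy branch).

    Parameters mirror the training protocol: Adam (lr 1e-3), up to 150
    epochs with early stopping after 15 epochs without validation-loss
    improvement (best weights restored), MSE loss in regression mode and
    binary cross-entropy in classification mode.  ``encoder_weights`` (from a
    fitted :class:`KmerAutoencoder`) switches the encoder from random to
    pre-trained initialization; ``freeze_encoder`` restricts training to the
    layers downstream of the encoder.  ``epochs=0`` builds the network
    without training (random-weights baseline).
    """

    def __init__(self, n=32, variant="fc8+fc9", use_occupancy=False,
                 mode="regression", encoder_weights=None, freeze_encoder=False,
                 epochs=150, patience=15, batch_size=64, learning_rate=1e-3,
                 l2=1e-4, validation_fraction=0.25, kernel=5, seed=0,
                 verbose=0):
        self.n = n
        self.variant = variant
        self.use_occupancy = use_occupancy
        self.mode = mode
        self.encoder_weights = encoder_weights
        self.freeze_encoder = freeze_encoder
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.validation_fraction = validation_fraction
        self.kernel = kernel
        self.seed = seed
        self.verbose = verbose

    # -- internals ----------------------------------------------------------
    def _build(self, rng):
        fcs = VARIANT_FCS[self.variant]
        net = CSNetwork(self.n, fcs, self.use_occupancy, self.kernel, rng)
        if self.encoder_weights is not None:
            net.encoder.set_weights(self.encoder_weights)
        return net

    def _loss(self, pred, y):
        if self.mode == "classification":
            return bce_with_logits_loss(pred, y)
        return mse_loss(pred, y)

    def _eval_loss(self, net, Xs, occ, y):
        pred = net.forward(Xs, occ, train=False)
        return self._loss(pred, y.reshape(-1, 1))[0]

    def fit(self, X, y, validation_data=None):
        Xs, occ = _split_X(X, self.n, self.use_occupancy)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xs):
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = 4 * self.n + (1 if self.use_occupancy else 0)
        rng = np.random.default_rng(self.seed)
        net = self.network_ = self._build(rng)
        self.history_ = {"train_loss": [], "val_loss": []}
        if self.epochs == 0:
            return self  # random-weights baseline

        if validation_data is not None:
            Xv, yv = validation_data
            Xvs, occv = _split_X(Xv, self.n, self.use_occupancy)
            yv = np.asarray(yv, dtype=float).ravel()
            tr = np.arange(len(y))
        else:
            order = rng.permutation(len(y))
            n_val = max(1, int(round(self.validation_fraction * len(y))))
            val, tr = order[:n_val], order[n_val:]
            Xvs = Xs[val]
            occv = occ[val] if occ is not None else None
            yv = y[val]

        opt = Adam(net.trainable_layers(self.freeze_encoder),
                   lr=self.learning_rate, l2=self.l2)
        best_loss, best_weights, stall = np.inf, None, 0
        for epoch in range(self.epochs):
            perm = rng.permutation(tr)
            total = 0.0
            for lo in range(0, len(perm), self.batch_size):
                b = perm[lo:lo + self.batch_size]
                ob = occ[b] if occ is not None else None
                pred = net.forward(Xs[b], ob, train=True,
                                   freeze_encoder=self.freeze_encoder)
                loss, grad = self._loss(pred, y[b].reshape(-1, 1))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting {lo} (lr={self.learning_rate})")
                net.backward(grad, freeze_encoder=self.freeze_encoder)
                opt.step()
                total += loss * len(b)
            val_loss = self._eval_loss(net, Xvs, occv, yv)
            self.history_["train_loss"].append(total / len(tr))
            self.history_["val_loss"].append(val_loss)
            if self.verbose:
                print(f"[fit] epoch {epoch + 1} train "
                      f"{self.history_['train_loss'][-1]:.4f} val {val_loss:.4f}")
            if val_loss < best_loss - 1e-9:
                best_loss, best_weights, stall = val_loss, net.get_weights(), 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_weights is not None:
            net.set_weights(best_weights)
        self.best_val_loss_ = best_loss
        return self

    def predict(self, X):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        Xs, occ = _split_X(X, self.n, self.use_occupancy)
        out = self.network_.forward(Xs, occ, train=False).ravel()
        if self.mode == "classification":
            return sigmoid(out)
        return out


# ---------------------------------------------------------------------------
# spec-level wrappers

@dataclass
class TrainedModel:
    estimator: GuideActivityRegressor
    spec: ModelSpec
    config: TrainConfig
    history: dict
    test_indices: np.ndarray
    test_predictions: np.ndarray
    test_targets: np.ndarray
    provenance: dict = field(default_factory=dict)


def pretrain_cae(kmers, spec: ModelSpec, config: TrainConfig,
                 verbose: int = 0, return_estimator: bool = False):
    """Pre-train the autoencoder on genome k-mers; returns encoder weights
    (or the fitted :class:`KmerAutoencoder` with ``return_estimator=True``)."""
    kmers = list(kmers) if not isinstance(kmers, np.ndarray) else kmers
    if len(kmers) == 0:
        raise ValueError("empty k-mer set: nothing to pre-train on")
    cae = KmerAutoencoder(n=spec.n, kernel=spec.kernel, epochs=config.cae_epochs,
                          batch_size=config.cae_batch_size,
                          learning_rate=config.learning_rate, l2=spec.l2,
                          seed=config.seed, verbose=verbose)
    cae.fit(kmers)
    return cae if return_estimator else cae.encoder_weights_


def build_predictor(spec: ModelSpec, encoder_weights=None,
                    variant: str | None = None,
                    freeze_encoder: bool = False,
                    config: TrainConfig | None = None) -> GuideActivityRegressor:
    """Configured (unfitted) predictor for a spec/ablation variant."""
    config = config or TrainConfig()
    variant = variant or spec.variant
    if spec.use_occupancy and variant == "encoder_only" and encoder_weights is None:
        pass  # allowed: occupancy can merge straight onto the flatten layer
    return GuideActivityRegressor(
        n=spec.n, variant=variant, use_occupancy=spec.use_occupancy,
        mode=spec.mode, encoder_weights=encoder_weights,
        freeze_encoder=freeze_encoder, epochs=config.epochs,
        patience=config.patience, batch_size=config.batch_size,
        learning_rate=config.learning_rate, l2=spec.l2, kernel=spec.kernel,
        seed=config.seed)


def train_predictor(spec: ModelSpec, dataset, config: TrainConfig,
                    encoder_weights=None, freeze_encoder=False) -> TrainedModel:
    """Train on a (windows, occupancy, cs) dataset with a seeded 60/20/20
    train/validation/test split; returns held-out test predictions."""
    windows, occupancy, cs = dataset
    y = np.asarray(cs, dtype=float).ravel()
    if len(y) < 100:
        raise ValueError("dataset too small (< 100 examples)")
    X = pack_X(windows, occupancy if spec.use_occupancy else None)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(y))
    n_tr = int(round(config.split[0] * len(y)))
    n_val = int(round(config.split[1] * len(y)))
    tr, val, te = order[:n_tr], order[n_tr:n_tr + n_val], order[n_tr + n_val:]
    est = build_predictor(spec, encoder_weights=encoder_weights,
                          freeze_encoder=freeze_encoder, config=config)
    est.fit(X[tr], y[tr], validation_data=(X[val], y[val]))
    preds = est.predict(X[te]) if len(te) else np.array([])
    return TrainedModel(est, spec, config, est.history_, te, preds, y[te],
                        provenance={"pretrained": encoder_weights is not None,
                                    "frozen_encoder": bool(freeze_encoder)})


def predict_cs(model, windows, occupancy=None) -> np.ndarray:
    """Predict CS for guide context windows (strings or one-hot arrays)."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    if est.use_occupancy and occupancy is None:
        raise ValueError("this model requires occupancy values")
    X = pack_X(windows, occupancy if est.use_occupancy else None)
    return est.predict(X)


# ---------------------------------------------------------------------------
# persistence: npz weights + json sidecar

def save_model(est: GuideActivityRegressor, prefix: str) -> None:
    flat = {}
    for part, states in est.network_.get_weights().items():
        for i, d in enumerate(states):
            for k, v in d.items():
                flat[f"{part}/{i}/{k}"] = v
    np.savez(prefix + ".weights.npz", **flat)
    params = {k: v for k, v in est.get_params().items()
              if k != "encoder_weights"}
    with open(prefix + ".json", "w") as fh:
        json.dump({"params": params,
                   "pretrained": est.encoder_weights is not None}, fh, indent=1)


def load_model(prefix: str) -> GuideActivityRegressor:
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    est = GuideActivityRegressor(**meta["params"])
    est.network_ = est._build(np.random.default_rng(est.seed))
    data = np.load(prefix + ".weights.npz")
    # layers without parameters (ReLU, pooling) have no npz entries: start
    # from the freshly built network's state and overwrite what was saved
    packed = est.network_.get_weights()
    for key in data.files:
        part, i, k = key.split("/")
        packed[part][int(i)][k] = data[key]
    est.network_.set_weights(packed)
    est.n_features_in_ = 4 * est.n + (1 if est.use_occupancy else 0)
    est.history_ = {"train_loss": [], "val_loss": []}
    return est
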