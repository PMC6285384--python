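"""The CDRP architectures: autoencoder (CDRP-A) and multi-task net (CDRP-N).

CDRP-A distills the clinical risk call: an autoencoder trained by mean
squared reconstruction error on the expression of the genes most associated
with the High-Risk label (top ⌈2%⌉ of features by ANOVA F-score, 250 of
12,464 at the reference cohort scale).  Its encoder stacks two 128-node tanh
layers and a 64-node linear code layer; the decoder mirrors the encoder and
is discarded after training.  The 64-dim code is the *HR embedding*.

CDRP-N predicts the two prognostic endpoints jointly: a shared trunk of
256/128/64-node ReLU layers feeds, optionally concatenated with the HR
embedding (64 + 64 = 128-wide merge), an event-free-survival branch (one
8-node ReLU layer) and an overall-survival branch (32- and 16-node ReLU
layers), each closed by a 2-way softmax.  No dropout or batch normalization
anywhere.  Training minimizes the weighted sum of the per-task categorical
cross-entropies (EFS weight 1.0, OS weight 2.0) with Adadelta (η = 1, no lr
decay), batch size 64, an inverse-frequency class-weight strategy, at most
500 epochs, and early stopping on an internal validation loss with
patience 4 and min-delta 1e-6.  The internal validation set is a stratified
10% carve-out of the fitting data, so no fold-test information is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .cohort import ExpressionMatrix
from .nn import Adadelta, Dense, RMSProp, categorical_crossentropy, softmax

__all__ = [
    "AutoencoderSpec", "MultiTaskSpec", "AETrainConfig", "MTTrainConfig",
    "TrainingConfig", "EmbeddingMatrix", "CDRPAutoencoder", "CDRPMultiTask",
    "AutoencoderTrainResult", "train_autoencoder", "encode",
    "train_multitask", "predict", "extract_activations",
    "autoencoder_input_dim", "save_checkpoint", "load_checkpoint",
]

LAYER_WIDTHS = {
    "shared_64": 64,
    "merge_128": 128,
    "os_branch_32": 32,
    "efs_branch_8": 8,
    "ae_code_64": 64,
}


def autoencoder_input_dim(n_features: int, fraction: float = 0.02) -> int:
    """Width of the CDRP-A input layer: top ⌈fraction · n_features⌉ genes."""
    return max(1, math.ceil(fraction * n_features))


@dataclass(frozen=True)
class AutoencoderSpec:
    input_dim: int
    hidden_dims: tuple = (128, 128)
    code_dim: int = 64

    @property
    def decoder_dims(self) -> tuple:
        return tuple(reversed(self.hidden_dims))


@dataclass(frozen=True)
class MultiTaskSpec:
    input_dim: int
    shared_dims: tuple = (256, 128, 64)
    efs_branch: tuple = (8,)
    os_branch: tuple = (32, 16)
    use_embedding: bool = True
    embedding_dim: int = 64

    @property
    def merge_dim(self) -> int:
        base = self.shared_dims[-1]
        return base + self.embedding_dim if self.use_embedding else base


@dataclass
class AETrainConfig:
    """RMSProp / mse, fixed epoch count, no stopping rule."""

    epochs: int = 2000
    batch_size: int = 64
    lr: float = 1e-3


@dataclass
class MTTrainConfig:
    """Adadelta / categorical cross-entropy with early stopping."""

    max_epochs: int = 500
    batch_size: int = 64
    lr: float = 1.0
    loss_weights: dict = field(default_factory=lambda: {"efs": 1.0, "os": 2.0})
    class_weights: bool = True
    patience: int = 4
    min_delta: float = 1e-6
    val_fraction: float = 0.1


@dataclass
class TrainingConfig:
    ae: AETrainConfig = field(default_factory=AETrainConfig)
    mt: MTTrainConfig = field(default_factory=MTTrainConfig)
    seed: int = 0


@dataclass
class EmbeddingMatrix:
    """Samples × d activations of a named hidden layer."""

    values: np.ndarray
    layer_name: str
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.layer_name in LAYER_WIDTHS:
            d = LAYER_WIDTHS[self.layer_name]
            if self.values.shape[1] != d:
                raise ValueError(
                    f"layer {self.layer_name!r} has width {d}, "
                    f"got {self.values.shape[1]}"
                )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("embedding rows and sample ids disagree")


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# CDRP-A


class CDRPAutoencoder:
    """Symmetric dense autoencoder; only the encoder survives training."""

    def __init__(self, spec: AutoencoderSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.hidden_dims]
        self.encoder = [
            Dense(dims[i], dims[i + 1], "tanh", rng)
            for i in range(len(dims) - 1)
        ]
        self.encoder.append(Dense(dims[-1], spec.code_dim, "linear", rng))
        ddims = [spec.code_dim, *spec.decoder_dims]
        self.decoder = [
            Dense(ddims[i], ddims[i + 1], "tanh", rng)
            for i in range(len(ddims) - 1)
        ]
        self.decoder.append(Dense(ddims[-1], spec.input_dim, "linear", rng))
        self.feature_ids: list | None = None
        self.history: list = []

    @property
    def layers(self):
        return [*self.encoder, *self.decoder]

    @property
    def layer_widths(self) -> list:
        return [self.spec.input_dim] + [l.n_out for l in self.layers]

    def reconstruct(self, X: np.ndarray, store: bool = False) -> np.ndarray:
        a = X
        for layer in self.layers:
            a = layer.forward(a, store=store)
        return a

    def encode_values(self, X: np.ndarray) -> np.ndarray:
        a = X
        for layer in self.encoder:
            a = layer.forward(a, store=False)
        return a

    def fit(self, X: np.ndarray, cfg: AETrainConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        opt = RMSProp(self.layers, lr=cfg.lr)
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = X[idx]
                recon = self.reconstruct(xb, store=True)
                err = recon - xb
                loss = float(np.mean(err * err))
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"autoencoder loss became {loss} at epoch {epoch}"
                    )
                for layer in self.layers:
                    layer.zero_grad()
                grad = 2.0 * err / err.size
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()
                total += loss * len(idx)
            self.history.append(total / n)
        return self

    def mse(self, X: np.ndarray) -> float:
        err = self.reconstruct(X) - X
        return float(np.mean(err * err))


@dataclass
class AutoencoderTrainResult:
    model: CDRPAutoencoder
    reconstruction_mse: float


def train_autoencoder(x: ExpressionMatrix | np.ndarray,
                      cfg: TrainingConfig | None = None,
                      eval_x=None) -> AutoencoderTrainResult:
    """Train CDRP-A on an (already standardized, feature-restricted) matrix.

    `eval_x` optionally supplies held-out samples for the reported
    reconstruction mse; otherwise the training matrix is used.
    """
    cfg = cfg or TrainingConfig()
    if isinstance(x, ExpressionMatrix):
        X, feature_ids = x.values, list(x.gene_ids)
    else:
        X, feature_ids = np.asarray(x, dtype=float), None
    model = CDRPAutoencoder(AutoencoderSpec(input_dim=X.shape[1]),
                            seed=cfg.seed)
    model.feature_ids = feature_ids
    model.fit(X, cfg.ae, seed=cfg.seed + 1)
    E = eval_x.values if isinstance(eval_x, ExpressionMatrix) else eval_x
    mse = model.mse(np.asarray(E, dtype=float) if E is not None else X)
    return AutoencoderTrainResult(model=model, reconstruction_mse=mse)


def encode(model: CDRPAutoencoder, x: ExpressionMatrix | np.ndarray
           ) -> EmbeddingMatrix:
    """Run the encoder only; the decoder is never invoked."""
    if isinstance(x, ExpressionMatrix):
        if model.feature_ids is not None and \
                list(x.gene_ids) != model.feature_ids:
            raise ValueError("feature set differs from autoencoder training")
        X, ids = x.values, list(x.sample_ids)
    else:
        X = np.asarray(x, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"expected {model.spec.input_dim} features, got {X.shape[1]}"
        )
    return EmbeddingMatrix(model.encode_values(X), "ae_code_64", ids)


# ---------------------------------------------------------------------------
# CDRP-N


class CDRPMultiTask:
    """Shared-trunk two-branch classifier for the EFS and OS endpoints."""

    def __init__(self, spec: MultiTaskSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.shared_dims]
        self.trunk = [
            Dense(dims[i], dims[i + 1], "relu", rng)
            for i in range(len(dims) - 1)
        ]
        m = spec.merge_dim
        edims = [m, *spec.efs_branch]
        self.efs_layers = [
            Dense(edims[i], edims[i + 1], "relu", rng)
            for i in range(len(edims) - 1)
        ]
        self.efs_layers.append(Dense(edims[-1], 2, "linear", rng))
        odims = [m, *spec.os_branch]
        self.os_layers = [
            Dense(odims[i], odims[i + 1], "relu", rng)
            for i in range(len(odims) - 1)
        ]
        self.os_layers.append(Dense(odims[-1], 2, "linear", rng))
        self.history: dict = {"loss": [], "val_loss": []}

    @property
    def layers(self):
        return [*self.trunk, *self.efs_layers, *self.os_layers]

    @property
    def layer_widths(self) -> dict:
        return {
            "input": self.spec.input_dim,
            "shared": [l.n_out for l in self.trunk],
            "merge": self.spec.merge_dim,
            "efs_branch": [l.n_out for l in self.efs_layers],
            "os_branch": [l.n_out for l in self.os_layers],
        }

    # forward ---------------------------------------------------------------

    def _merge(self, X, embedding):
        a = X
        acts = {}
        for layer in self.trunk:
            a = layer.forward(a, store=True)
        acts["shared_64"] = a
        if self.spec.use_embedding:
            if embedding is None:
                raise ValueError("model expects an HR embedding input")
            if embedding.shape[0] != X.shape[0]:
                raise ValueError("embedding rows misaligned with input rows")
            merged = np.concatenate([a, embedding], axis=1)
        else:
            if embedding is not None:
                raise ValueError("embedding passed to an embedding-free model")
            merged = a
        acts["merge"] = merged
        return merged, acts

    def forward(self, X, embedding=None):
        merged, acts = self._merge(X, embedding)
        a = merged
        for layer in self.efs_layers[:-1]:
            a = layer.forward(a, store=True)
        acts["efs_branch_8"] = a
        acts["efs_probs"] = softmax(self.efs_layers[-1].forward(a, store=True))
        a = merged
        a = self.os_layers[0].forward(a, store=True)
        acts["os_branch_32"] = a
        for layer in self.os_layers[1:-1]:
            a = layer.forward(a, store=True)
        acts["os_branch_16"] = a
        acts["os_probs"] = softmax(self.os_layers[-1].forward(a, store=True))
        return acts

    # loss / training -------------------------------------------------------

    @staticmethod
    def _onehot(y):
        out = np.zeros((len(y), 2))
        out[np.arange(len(y)), y] = 1.0
        return out

    @staticmethod
    def class_weight_map(y):
        """Inverse-frequency weights w_c = n / (2 · n_c)."""
        n = len(y)
        return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}

    def combined_loss(self, X, y_efs, y_os, embedding=None,
                      sample_w=None, loss_weights=None):
        lw = loss_weights or {"efs": 1.0, "os": 2.0}
        acts = self.forward(X, embedding)
        sw_e = sw_o = None
        if sample_w is not None:
            sw_e, sw_o = sample_w
        ce_e = categorical_crossentropy(acts["efs_probs"], self._onehot(y_efs), sw_e)
        ce_o = categorical_crossentropy(acts["os_probs"], self._onehot(y_os), sw_o)
        return lw["efs"] * ce_e + lw["os"] * ce_o, acts

    def _backward_batch(self, acts, y_efs, y_os, sw_e, sw_o, lw):
        B = len(y_efs)
        for layer in self.layers:
            layer.zero_grad()
        d_efs = (acts["efs_probs"] - self._onehot(y_efs)) / B * lw["efs"]
        if sw_e is not None:
            d_efs *= sw_e[:, None]
        grad = d_efs
        for layer in reversed(self.efs_layers):
            grad = layer.backward(grad)
        grad_merge = grad
        d_os = (acts["os_probs"] - self._onehot(y_os)) / B * lw["os"]
        if sw_o is not None:
            d_os *= sw_o[:, None]
        grad = d_os
        for layer in reversed(self.os_layers):
            grad = layer.backward(grad)
        grad_merge = grad_merge + grad
        shared_w = self.spec.shared_dims[-1]
        grad = grad_merge[:, :shared_w]  # embedding input receives no update
        for layer in reversed(self.trunk):
            grad = layer.backward(grad)

    def fit(self, X, y_efs, y_os, embedding=None,
            cfg: MTTrainConfig | None = None, seed: int = 0,
            validation=None):
        """Train with early stopping on a monitored validation loss.

        `validation` may be a tuple (X_val, efs_val, os_val, emb_val); by
        default a stratified `val_fraction` carve-out of the fitting data is
        used, so fold-test data is never consulted.
        """
        cfg = cfg or MTTrainConfig()
        X = np.asarray(X, dtype=float)
        y_efs = np.asarray(y_efs, dtype=int)
        y_os = np.asarray(y_os, dtype=int)
        for name, y in (("efs", y_efs), ("os", y_os)):
            if len(np.unique(y)) < 2:
                raise ValueError(f"training labels for task {name!r} are single-class")
        rng = np.random.default_rng(seed)

        if validation is None:
            X, y_efs, y_os, embedding, val = self._carve_validation(
                X, y_efs, y_os, embedding, cfg.val_fraction, seed)
        else:
            val = validation

        cw = None
        if cfg.class_weights:
            cw_e = self.class_weight_map(y_efs)
            cw_o = self.class_weight_map(y_os)
            cw = (np.array([cw_e[v] for v in y_efs]),
                  np.array([cw_o[v] for v in y_os]))

        opt = Adadelta(self.layers, lr=cfg.lr)
        n = X.shape[0]
        best = np.inf
        wait = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                sw_e = cw[0][idx] if cw else None
                sw_o = cw[1][idx] if cw else None
                emb_b = embedding[idx] if embedding is not None else None
                loss, acts = self.combined_loss(
                    X[idx], y_efs[idx], y_os[idx], emb_b,
                    (sw_e, sw_o), cfg.loss_weights)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"multitask loss became {loss} at epoch {epoch}")
                self._backward_batch(acts, y_efs[idx], y_os[idx],
                                     sw_e, sw_o, cfg.loss_weights)
                opt.step()
                total += loss * len(idx)
            self.history["loss"].append(total / n)

            vX, ve, vo, vemb = val
            val_loss, _ = self.combined_loss(vX, ve, vo, vemb,
                                             None, cfg.loss_weights)
            self.history["val_loss"].append(val_loss)
            if val_loss < best - cfg.min_delta:
                best = val_loss
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        return self

    @staticmethod
    def _carve_validation(X, y_efs, y_os, embedding, fraction, seed):
        n = X.shape[0]
        strat = y_efs * 2 + y_os
        # stratify on the joint endpoint when every stratum allows it
        counts = np.bincount(strat)
        stratify = strat if (counts[counts > 0] >= 2).all() else None
        idx = np.arange(n)
        tr, va = train_test_split(
            idx, test_size=max(2, int(round(fraction * n))),
            random_state=seed % (2**32), stratify=stratify)
        # the carve-out must leave both classes in the gradient portion
        if len(np.unique(y_efs[tr])) < 2 or len(np.unique(y_os[tr])) < 2:
            tr, va = train_test_split(idx, test_size=2,
                                      random_state=seed % (2**32))
        emb_tr = embedding[tr] if embedding is not None else None
        emb_va = embedding[va] if embedding is not None else None
        val = (X[va], y_efs[va], y_os[va], emb_va)
        return X[tr], y_efs[tr], y_os[tr], emb_tr, val

    def predict_proba(self, X, embedding=None) -> dict:
        acts = self.forward(np.asarray(X, dtype=float), embedding)
        return {"efs": acts["efs_probs"], "os": acts["os_probs"]}

    def predict(self, X, embedding=None) -> dict:
        probs = self.predict_proba(X, embedding)
        return {task: p.argmax(axis=1) for task, p in probs.items()}


def train_multitask(x, labels: dict, embedding=None,
                    cfg: TrainingConfig | None = None,
                    validation=None) -> CDRPMultiTask:
    """Convenience wrapper building the spec from the data shapes."""
    cfg = cfg or TrainingConfig()
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    emb = None
    if embedding is not None:
        emb = embedding.values if isinstance(embedding, EmbeddingMatrix) \
            else np.asarray(embedding, float)
        if isinstance(embedding, EmbeddingMatrix) and \
                isinstance(x, ExpressionMatrix) and \
                embedding.sample_ids != x.sample_ids:
            raise ValueError("embedding sample ids misaligned with input")
    spec = MultiTaskSpec(input_dim=X.shape[1], use_embedding=emb is not None)
    model = CDRPMultiTask(spec, seed=cfg.seed)
    model.fit(X, labels["efs"], labels["os"], embedding=emb,
              cfg=cfg.mt, seed=cfg.seed + 1, validation=validation)
    return model


def predict(model: CDRPMultiTask, x, embedding=None) -> dict:
    """Per-task class probabilities and hard labels."""
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    emb = None
    if embedding is not None:
        emb = embedding.values if isinstance(embedding, EmbeddingMatrix) \
            else np.asarray(embedding, float)
    probs = model.predict_proba(X, emb)
    return {
        task: {"probs": p, "labels": p.argmax(axis=1)}
        for task, p in probs.items()
    }


def extract_activations(model, x, layer_name: str, embedding=None
                        ) -> EmbeddingMatrix:
    """Activations of a named hidden layer for downstream stratification."""
    if isinstance(model, CDRPAutoencoder):
        if layer_name != "ae_code_64":
            raise ValueError(f"autoencoder exposes 'ae_code_64', not {layer_name!r}")
        return encode(model, x)
    if layer_name not in ("shared_64", "merge_128", "os_branch_32", "efs_branch_8"):
        raise ValueError(f"unknown layer {layer_name!r}")
    if layer_name == "merge_128" and not model.spec.use_embedding:
        raise ValueError("merge_128 requires a model trained with the HR embedding")
    if isinstance(x, ExpressionMatrix):
        X, ids = x.values, list(x.sample_ids)
    else:
        X = np.asarray(x, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    emb = None
    if embedding is not None:
        emb = embedding.values if isinstance(embedding, EmbeddingMatrix) \
            else np.asarray(embedding, float)
    acts = model.forward(X, emb)
    key = "merge" if layer_name == "merge_128" else layer_name
    name = layer_name
    return EmbeddingMatrix(acts[key], name, ids)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model, directory) -> None:
    """Persist a trained net: weights archive + YAML architecture manifest.

    The manifest alone suffices to rebuild the graph; the sidecar ``.npz``
    holds the parameter arrays in layer order.
    """
    import yaml
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, CDRPAutoencoder):
        manifest = {
            "kind": "autoencoder",
            "spec": {"input_dim": model.spec.input_dim,
                     "hidden_dims": list(model.spec.hidden_dims),
                     "code_dim": model.spec.code_dim},
            "feature_ids": model.feature_ids,
        }
        layers = model.layers
    elif isinstance(model, CDRPMultiTask):
        manifest = {
            "kind": "multitask",
            "spec": {"input_dim": model.spec.input_dim,
                     "shared_dims": list(model.spec.shared_dims),
                     "efs_branch": list(model.spec.efs_branch),
                     "os_branch": list(model.spec.os_branch),
                     "use_embedding": model.spec.use_embedding,
                     "embedding_dim": model.spec.embedding_dim},
        }
        layers = model.layers
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    arrays = {}
    for i, layer in enumerate(layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    np.savez(directory / "weights.npz", **arrays)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_checkpoint(directory):
    """Rebuild a net from :func:`save_checkpoint` output."""
    import yaml
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    spec = manifest["spec"]
    if manifest["kind"] == "autoencoder":
        model = CDRPAutoencoder(AutoencoderSpec(
            input_dim=spec["input_dim"],
            hidden_dims=tuple(spec["hidden_dims"]),
            code_dim=spec["code_dim"]))
        model.feature_ids = manifest.get("feature_ids")
    else:
        model = CDRPMultiTask(MultiTaskSpec(
            input_dim=spec["input_dim"],
            shared_dims=tuple(spec["shared_dims"]),
            efs_branch=tuple(spec["efs_branch"]),
            os_branch=tuple(spec["os_branch"]),
            use_embedding=spec["use_embedding"],
            embedding_dim=spec["embedding_dim"]))
    with np.load(directory / "weights.npz") as arrays:
        for i, layer in enumerate(model.layers):
            layer.W = arrays[f"W{i}"]
            layer.b = arrays[f"b{i}"]
    return model
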