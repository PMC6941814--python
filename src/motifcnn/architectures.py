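"""The controlled CNN family and its training protocol.

All variants share the same skeleton — conv(30 x 19) -> conv(128 x 5) ->
dense(512) -> 12 sigmoid outputs, with batch-norm/ReLU/max-pool/dropout(0.1)
after each convolution and dropout(0.5) after the hidden dense layer — and
differ only in filter sizes and max-pool geometry.  In the coupled-pool
series the two pool sizes multiply to 100, so every member feeds an
identically sized dense layer and has an identical parameter count; what
varies is only where the spatial information bottleneck sits.  Training is
Adam (lr 3e-4, batch 100) on binary cross-entropy with L2 1e-6, up to 100
epochs, keeping the checkpoint with the lowest validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .nn.fused import FusedBNReLU
from .nn.layers import Conv1D, Dense, Dropout, Flatten, MaxPool1D, ReLU
from .nn.model import Adam, Sequential, TrainingError, bce_with_logits
from .simulate import SyntheticDataset


@dataclass(frozen=True)
class ConvBlockSpec:
    n_filters: int
    filter_size: int
    pool_size: int          # 1 means no pooling
    pool_stride: int
    stride: int = 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Complete geometry of one CNN variant."""

    name: str
    conv_layers: tuple[ConvBlockSpec, ...]
    dense_units: int = 512
    n_classes: int = 12
    dropout_conv: float = 0.1
    dropout_dense: float = 0.5
    l2_strength: float = 1e-6
    padding: Literal["same"] = "same"

    def to_dict(self) -> dict:
        return asdict(self)


_COUPLED = {1: (1, 100), 2: (2, 50), 4: (4, 25), 10: (10, 10),
            25: (25, 4), 50: (50, 2), 100: (100, 1)}


def _two_layer(name: str, f1: int, f2: int, pools: tuple[int, int],
               pool1_stride: int | None = None, n_filters1: int = 30
               ) -> ArchitectureSpec:
    p1, p2 = pools
    return ArchitectureSpec(name, (
        ConvBlockSpec(n_filters1, f1, p1, pool1_stride or p1),
        ConvBlockSpec(128, f2, p2, p2),
    ))


def variant_names() -> list[str]:
    names = [f"CNN-{p}" for p in _COUPLED]
    names += ["CNN_9-4", "CNN_9-25", "CNN_3-2", "CNN_3-50",
              "CNN-50-2", "CNN_19-1-2", "CNN-1-1-100"]
    return names


def make_variant(name: str, n_filters1: int = 30) -> ArchitectureSpec:
    """Build the named variant's spec; ``n_filters1`` widens the first layer.

    Coupled-pool variants are named ``CNN-<pool1>`` with pool sizes
    multiplying to 100; ``CNN_<k>-<pool1>`` changes the first-layer filter
    size to k; ``CNN-50-2`` pools with window 50 but stride 2 (then 50/50);
    ``CNN_19-1-2`` shrinks the second-layer filter to size 1; and
    ``CNN-1-1-100`` inserts a third conv layer with all pooling (size 100)
    deferred until after it.
    """
    if name.startswith("CNN-") and name[4:].isdigit():
        p1 = int(name[4:])
        if p1 in _COUPLED:
            return _two_layer(name, 19, 5, _COUPLED[p1], n_filters1=n_filters1)
    table = {
        "CNN_9-4": lambda: _two_layer(name, 9, 5, (4, 25), n_filters1=n_filters1),
        "CNN_9-25": lambda: _two_layer(name, 9, 5, (25, 4), n_filters1=n_filters1),
        "CNN_3-2": lambda: _two_layer(name, 3, 5, (2, 50), n_filters1=n_filters1),
        "CNN_3-50": lambda: _two_layer(name, 3, 5, (50, 2), n_filters1=n_filters1),
        "CNN-50-2": lambda: _two_layer(name, 19, 5, (50, 50), pool1_stride=2,
                                       n_filters1=n_filters1),
        "CNN_19-1-2": lambda: _two_layer(name, 19, 1, (2, 50),
                                         n_filters1=n_filters1),
        "CNN-1-1-100": lambda: ArchitectureSpec(name, (
            ConvBlockSpec(n_filters1, 19, 1, 1),
            ConvBlockSpec(128, 5, 1, 1),
            ConvBlockSpec(128, 5, 100, 100),
        )),
    }
    if name in table:
        return table[name]()
    raise ValueError(
        f"unknown variant {name!r}; valid names: {', '.join(variant_names())}")


class CNN(Sequential):
    """A built variant: the layer stack plus geometry bookkeeping."""

    def __init__(self, spec: ArchitectureSpec, input_length: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        layers = []
        self.spec = spec
        self.input_length = input_length
        self.conv_indices: list[int] = []   # index of Conv1D per block
        self.relu_indices: list[int] = []   # index of post-BN ReLU per block
        c_in, length = 4, input_length
        for bi, blk in enumerate(spec.conv_layers):
            self.conv_indices.append(len(layers))
            layers.append(Conv1D(c_in, blk.n_filters, blk.filter_size, rng, dtype,
                                 input_layer=(bi == 0)))
            self.relu_indices.append(len(layers))
            layers.append(FusedBNReLU(blk.n_filters, dtype=dtype))
            pool = MaxPool1D(blk.pool_size, blk.pool_stride)
            length = pool.out_length(length)
            if length < 1:
                raise ValueError(f"{spec.name}: pooling chain exhausts length")
            layers.append(pool)
            layers.append(Dropout(spec.dropout_conv))
            c_in = blk.n_filters
        self.flat_size = length * c_in
        layers.append(Flatten())
        layers.append(Dense(self.flat_size, spec.dense_units, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(spec.dropout_dense))
        layers.append(Dense(spec.dense_units, spec.n_classes, rng, dtype))
        super().__init__(layers)

    def conv_activations(self, x: np.ndarray, conv_layer: int,
                         batch_size: int = 512) -> np.ndarray:
        """Post-ReLU (pre-pool) feature maps of conv block ``conv_layer`` (1-based)."""
        idx = self.relu_indices[conv_layer - 1]
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward_to(x[i:i + batch_size], idx))
        return np.concatenate(out, axis=0)


def build_model(spec: ArchitectureSpec, input_length: int = 200,
                seed: int = 0, dtype=np.float32) -> CNN:
    """Instantiate a variant with He-initialised weights (seeded)."""
    return CNN(spec, input_length, np.random.default_rng(seed), dtype)


@dataclass
class TrainConfig:
    batch_size: int = 100
    max_epochs: int = 100
    learning_rate: float = 3e-4
    l2_strength: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1 and learning_rate > 0 required")


@dataclass
class TrainedModel:
    model: CNN
    spec: ArchitectureSpec
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1


def _dataset_to_channels_last(X: np.ndarray) -> np.ndarray:
    # stored (N, 4, L); the network wants (N, L, 4)
    return np.ascontiguousarray(np.transpose(X, (0, 2, 1)))


def _mean_loss(model: CNN, X: np.ndarray, y: np.ndarray,
               batch_size: int = 512, col: np.ndarray | None = None) -> float:
    total, n = 0.0, 0
    for i in range(0, X.shape[0], batch_size):
        c = col[i:i + batch_size] if col is not None else None
        logits = model.forward(X[i:i + batch_size], train=False, col0=c)
        loss, _ = bce_with_logits(logits, y[i:i + batch_size])
        total += loss * logits.shape[0]
        n += logits.shape[0]
    return total / n


def train(model: CNN, dataset: SyntheticDataset,
          config: TrainConfig | None = None, verbose: bool = False
          ) -> TrainedModel:
    """Train under the benchmark protocol with best-validation checkpointing.

    Early stopping is checkpoint selection: the run always lasts
    ``max_epochs`` epochs and the parameters with the lowest validation
    binary cross-entropy are restored at the end.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    Xtr, ytr = dataset.subset("train")
    Xva, yva = dataset.subset("validation")
    Xtr = _dataset_to_channels_last(Xtr)
    Xva = _dataset_to_channels_last(Xva)
    ytr32 = ytr.astype(np.float32)

    opt = Adam(model, lr=config.learning_rate, l2=config.l2_strength)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val, best_state, best_epoch = np.inf, None, -1
    n = Xtr.shape[0]

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Xtr[idx], train=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, ytr32[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"loss diverged at epoch {epoch}, batch {bi}")
            model.backward(dlogits)
            opt.step()
            running += loss * len(idx)
            seen += len(idx)
        val_loss = _mean_loss(model, Xva, yva)
        history["train_loss"].append(running / seen)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state()
        if verbose:
            print(f"epoch {epoch:3d}  train {running / seen:.4f}  val {val_loss:.4f}")
    if best_state is not None:
        model.load_state(best_state)
    return TrainedModel(model, model.spec, history, best_epoch)


def save_checkpoint(trained: TrainedModel, path: str) -> None:
    """Persist weights (npz) plus a JSON sidecar of spec and history."""
    import json
    from pathlib import Path

    p = Path(path)
    np.savez(p.with_suffix(".npz"),
             *[np.asarray(a) for a in trained.model.state()])
    sidecar = {"spec": trained.spec.to_dict(),
               "input_length": trained.model.input_length,
               "history": trained.history, "best_epoch": trained.best_epoch}
    p.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str) -> TrainedModel:
    """Rebuild a trained model from :func:`save_checkpoint` output."""
    import json
    from pathlib import Path

    p = Path(path)
    sidecar = json.loads(p.with_suffix(".json").read_text())
    sd = sidecar["spec"]
    spec = ArchitectureSpec(
        name=sd["name"],
        conv_layers=tuple(ConvBlockSpec(**blk) for blk in sd["conv_layers"]),
        dense_units=sd["dense_units"], n_classes=sd["n_classes"],
        dropout_conv=sd["dropout_conv"], dropout_dense=sd["dropout_dense"],
        l2_strength=sd["l2_strength"])
    model = build_model(spec, sidecar["input_length"])
    with np.load(p.with_suffix(".npz")) as z:
        model.load_state([z[k] for k in z.files])
    return TrainedModel(model, spec, sidecar["history"],
                        sidecar["best_epoch"])


def evaluate(trained: TrainedModel, dataset: SyntheticDataset,
             split: str = "test") -> dict:
    """Per-class AU-ROC / AU-PR on a split plus their unweighted means.

    A class without both positives and negatives in the split has no
    defined ranking metric; it is reported as NaN, excluded from the means,
    and a warning is emitted.
    """
    X, y = dataset.subset(split)
    if X.shape[0] == 0:
        raise ValueError(f"split {split!r} is empty")
    probs = trained.model.predict(_dataset_to_channels_last(X))
    n_classes = y.shape[1]
    auroc = np.full(n_classes, np.nan)
    aupr = np.full(n_classes, np.nan)
    for c in range(n_classes):
        if 0 < y[:, c].sum() < y.shape[0]:
            auroc[c] = roc_auc_score(y[:, c], probs[:, c])
            aupr[c] = average_precision_score(y[:, c], probs[:, c])
        else:
            warnings.warn(f"class {c} has a single label value in {split!r}; "
                          "metric undefined", stacklevel=2)
    return {
        "auroc": auroc,
        "aupr": aupr,
        "mean_auroc": float(np.nanmean(auroc)),
        "mean_aupr": float(np.nanmean(aupr)),
    }
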