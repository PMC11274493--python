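"""Pretraining, latent extraction and persistence for the CNN extractors."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radguide.deepnet._models import ArchConfig, Network, build_extractor
from radguide.deepnet._nn import Adam, BatchNorm3d, Layer, cross_entropy, softmax
from radguide.io_core import CLASS_LABELS, FeatureTable, Volume


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 4
    lr: float = 1e-3
    seed: int = 0


@dataclass
class TrainedExtractor:
    network: Network
    classes: tuple[str, ...]
    log: pd.DataFrame          # per-epoch mean loss
    train_config: TrainConfig

    @property
    def n_latent(self) -> int:
        return self.network.n_latent


def _stack(volumes: list[Volume]) -> np.ndarray:
    return np.stack([v.data for v in volumes]).astype(np.float32)[:, None]


def pretrain(network: Network, volumes: list[Volume], labels: list[str],
             train_config: TrainConfig | None = None) -> TrainedExtractor:
    """Cross-entropy pretraining on the pretraining split.

    Deterministic given (architecture seed, training seed, data): mini-batch
    order comes from a dedicated RNG, all kernels are plain NumPy. Raises on
    single-class splits and aborts on non-finite loss.
    """
    cfg = train_config or TrainConfig()
    classes = tuple(c for c in CLASS_LABELS if c in set(labels))
    if len(classes) < 2:
        raise ValueError("pretraining split must contain >= 2 classes")
    y = np.array([classes.index(l) for l in labels])
    x = _stack(volumes)
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    opt = Adam(network.params(), lr=cfg.lr)
    losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = network.forward_logits(x[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}")
            network.backward_logits(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    log = pd.DataFrame({"epoch": np.arange(cfg.epochs), "loss": losses})
    return TrainedExtractor(network=network, classes=classes, log=log,
                            train_config=cfg)


def predict_classes(trained: TrainedExtractor, volumes: list[Volume],
                    batch_size: int = 8) -> tuple[list[str], np.ndarray]:
    """Evaluation-mode class predictions of the pretrained head."""
    x = _stack(volumes)
    probs = []
    for start in range(0, len(x), batch_size):
        logits = trained.network.forward_logits(x[start:start + batch_size], train=False)
        probs.append(softmax(logits))
    p = np.vstack(probs)
    return [trained.classes[i] for i in p.argmax(1)], p


def extract_latent(trained: TrainedExtractor, volume: Volume) -> np.ndarray:
    """Latent feature vector of one subject (flattened last-conv map)."""
    net = trained.network
    if volume.data.shape != tuple(net.config.input_shape):
        raise ValueError(
            f"volume shape {volume.data.shape} != network input {net.config.input_shape}")
    return net.latent(volume.data[None, None])[0]


def _walk_layers(obj):
    """Depth-first walk over all Layer objects reachable from ``obj``."""
    if isinstance(obj, Layer):
        yield obj
        values = vars(obj).values()
    elif isinstance(obj, (list, tuple)):
        values = obj
    else:
        return
    for v in values:
        if isinstance(v, (Layer, list, tuple)):
            yield from _walk_layers(v)


def _state_arrays(network: Network) -> list[np.ndarray]:
    """All learned arrays in deterministic order (params + BN statistics)."""
    arrays = [p for p, _ in network.params()]
    for layer in _walk_layers([network.features, network.head]):
        if isinstance(layer, BatchNorm3d):
            arrays += [layer.running_mean, layer.running_var]
    return arrays


def save_extractor(trained: TrainedExtractor, out_dir: str | Path) -> Path:
    """Persist architecture config, training log and learned parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "arch": dataclasses.asdict(trained.network.config),
        "train": dataclasses.asdict(trained.train_config),
        "classes": list(trained.classes),
    }
    (out / "extractor.json").write_text(json.dumps(meta, indent=2))
    trained.log.to_csv(out / "training_log.csv", index=False)
    arrays = _state_arrays(trained.network)
    np.savez(out / "weights.npz", **{f"a{i}": a for i, a in enumerate(arrays)})
    return out


def load_extractor(model_dir: str | Path) -> TrainedExtractor:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "extractor.json").read_text())
    arch = meta["arch"]
    arch["input_shape"] = tuple(arch["input_shape"])
    network = build_extractor(ArchConfig(**arch))
    with np.load(model_dir / "weights.npz") as z:
        arrays = _state_arrays(network)
        if len(arrays) != len(z.files):
            raise ValueError("weight file does not match the architecture")
        for i, a in enumerate(arrays):
            a[...] = z[f"a{i}"]
    log = pd.read_csv(model_dir / "training_log.csv")
    return TrainedExtractor(network=network, classes=tuple(meta["classes"]),
                            log=log, train_config=TrainConfig(**meta["train"]))


def latent_table(trained: TrainedExtractor, volumes: list[Volume],
                 batch_size: int = 8) -> FeatureTable:
    """Latent feature table for a list of subjects."""
    net = trained.network
    rows = []
    for start in range(0, len(volumes), batch_size):
        batch = volumes[start:start + batch_size]
        x = _stack(batch)
        rows.append(net.latent(x))
    df = pd.DataFrame(np.vstack(rows), columns=net.latent_names(),
                      index=[v.id for v in volumes])
    df.index.name = "subject_id"
    return FeatureTable(df)
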