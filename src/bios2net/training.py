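"""Dataset handling, the training loop, accuracy metrics, and embedding export.

The train/test split follows a per-fold-group rule: groups with more than
100 members contribute 20 test proteins; groups below 30 members contribute
ceil(0.3·n); sizes 30–100 interpolate linearly between those two regimes
(9 test proteins at n = 30, 20 at n = 100, rounded). Normalization statistics
are always fitted on the training clouds only.

Two accuracies are tracked: *simple accuracy* (correct / total) and *mean
class accuracy* (unweighted mean of per-class simple accuracies), and runs
are summarized by the mean ± population standard deviation of the test
accuracies over the final epochs of a fixed epoch budget.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import PointCloud
from .features import (
    NormalizationStats,
    annotate,
    apply_normalization,
    featurize,
    fit_normalization,
)
from .nn.autograd import Tensor, softmax
from .nn.losses import combined_loss
from .nn.model import BioS2Net, ModelConfig, SALayerConfig
from .nn.optim import Adam
from .sampling import AugmentationConfig, augment, sample_points
from .structure_io import parse_structure, read_pssm, zero_pssm


# -- manifest --------------------------------------------------------------

@dataclass
class ManifestEntry:
    identifier: str
    structure_path: Path
    pssm_path: Path | None
    label: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]

    def groups(self) -> dict[str, list[ManifestEntry]]:
        out: dict[str, list[ManifestEntry]] = {}
        for entry in self.entries:
            out.setdefault(entry.label, []).append(entry)
        return out

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        root = path.parent
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["id", "structure_path", "pssm_path", "label"]:
                raise ValueError("manifest header must be "
                                 "id/structure_path/pssm_path/label")
            for line in fh:
                if not line.strip():
                    continue
                sid, spath, ppath, label = line.rstrip("\n").split("\t")[:4]
                entries.append(ManifestEntry(
                    sid, root / spath,
                    (root / ppath) if ppath else None, label))
        if not entries:
            raise ValueError("empty manifest")
        return cls(entries)


def test_set_size(group_size: int) -> int:
    """Per-group test-set size: 20 above 100, ceil(0.3·n) below 30, linear between."""
    n = group_size
    if n > 100:
        return 20
    if n < 30:
        return math.ceil(0.3 * n)
    # linear interpolation between (30, 9) and (100, 20), rounding half up
    return math.floor(9 + (n - 30) * 11 / 70 + 0.5)


def split_dataset(manifest: DatasetManifest,
                  seed: int) -> tuple[DatasetManifest, DatasetManifest]:
    """Seeded per-group partition into train and test manifests."""
    rng = np.random.default_rng(seed)
    train: list[ManifestEntry] = []
    test: list[ManifestEntry] = []
    for label in sorted(manifest.groups()):
        members = manifest.groups()[label]
        if len(members) == 1:
            warnings.warn(f"group {label!r} has a single member; kept in train",
                          stacklevel=2)
            train.extend(members)
            continue
        n_test = test_set_size(len(members))
        order = rng.permutation(len(members))
        test.extend(members[i] for i in sorted(order[:n_test]))
        train.extend(members[i] for i in sorted(order[n_test:]))
    return DatasetManifest(train), DatasetManifest(test)


# -- featurization of manifest entries ------------------------------------

def load_entry_cloud(entry: ManifestEntry, asa_points: int = 960) -> PointCloud:
    """Parse, annotate and featurize one manifest entry into a raw cloud."""
    structure = parse_structure(entry.structure_path.read_text(),
                                identifier=entry.identifier)
    if entry.pssm_path is not None and entry.pssm_path.exists():
        pssm = read_pssm(entry.pssm_path.read_text(), structure.length)
    else:
        pssm = zero_pssm(structure.length)
    annotation = annotate(structure, asa_points=asa_points)
    return featurize(structure, pssm, annotation, label=entry.label)


def prepare_clouds(manifest: DatasetManifest,
                   asa_points: int = 960) -> list[PointCloud]:
    return [load_entry_cloud(e, asa_points) for e in manifest.entries]


# -- metrics ---------------------------------------------------------------

def evaluate(predictions: list[tuple]) -> tuple[float, float]:
    """(simple accuracy, mean class accuracy) from (true, predicted) pairs."""
    if not predictions:
        raise ValueError("no predictions to evaluate")
    true = np.array([t for t, _ in predictions])
    pred = np.array([p for _, p in predictions])
    simple = float((true == pred).mean())
    per_class = [float((pred[true == c] == c).mean())
                 for c in np.unique(true)]
    return simple, float(np.mean(per_class))


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    test_simple: float
    test_mean_class: float
    head_accuracies: dict[str, float] = field(default_factory=dict)


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def append(self, record: EpochRecord) -> None:
        if record.epoch != len(self.records) + 1:
            raise ValueError("epochs must be contiguous from 1")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)


def summarize_history(history: TrainingHistory,
                      last_k: int = 20) -> dict[str, float]:
    """Mean ± population std of the test accuracies over the final epochs."""
    if len(history) < last_k:
        raise ValueError(
            f"history has {len(history)} epochs, need at least {last_k}")
    tail = history.records[-last_k:]
    simple = np.array([r.test_simple for r in tail])
    mclass = np.array([r.test_mean_class for r in tail])
    return {
        "simple_accuracy_mean": float(simple.mean()),
        "simple_accuracy_std": float(simple.std()),
        "mean_class_accuracy_mean": float(mclass.mean()),
        "mean_class_accuracy_std": float(mclass.std()),
    }


# -- training --------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    asa_points: int = 960


@dataclass
class FittedModel:
    model: BioS2Net
    stats: NormalizationStats
    classes: list[str]
    model_config: ModelConfig


def _batch_tensor(clouds: list[PointCloud]) -> Tensor:
    return Tensor(np.stack([c.points for c in clouds]).astype(np.float32))


def _predict(model: BioS2Net, clouds: list[PointCloud],
             batch_size: int = 64) -> dict[str, np.ndarray]:
    model.set_training(False)
    heads: dict[str, list[np.ndarray]] = {}
    for i in range(0, len(clouds), batch_size):
        out = model(_batch_tensor(clouds[i:i + batch_size]))
        for key in ("main_logits", "struct_logits", "temporal_logits"):
            if out.get(key) is not None:
                heads.setdefault(key, []).append(
                    out[key].data.argmax(axis=1))
    model.set_training(True)
    return {k: np.concatenate(v) for k, v in heads.items()}


def train(manifest: DatasetManifest, model_config: ModelConfig,
          train_config: TrainConfig, seed: int,
          clouds: list[PointCloud] | None = None,
          test_manifest: DatasetManifest | None = None,
          test_clouds: list[PointCloud] | None = None,
          ) -> tuple[FittedModel, TrainingHistory]:
    """Fit the network on a manifest; returns the fitted model and history.

    When ``test_manifest`` is None the manifest is split internally with the
    per-group rule. Pre-featurized raw clouds can be supplied to skip
    featurization (orders must match the manifests).
    """
    if test_manifest is None:
        train_manifest, test_manifest = split_dataset(manifest, seed)
        if clouds is not None or test_clouds is not None:
            raise ValueError("pre-featurized clouds require an explicit split")
    else:
        train_manifest = manifest

    if clouds is None:
        clouds = prepare_clouds(train_manifest, train_config.asa_points)
    if test_clouds is None:
        test_clouds = prepare_clouds(test_manifest, train_config.asa_points)

    classes = sorted({e.label for e in train_manifest.entries})
    class_index = {c: i for i, c in enumerate(classes)}
    y_train = np.array([class_index[e.label] for e in train_manifest.entries])
    y_test = np.array([class_index[e.label] for e in test_manifest.entries])

    stats = fit_normalization(clouds)
    norm_train = [apply_normalization(c, stats) for c in clouds]
    norm_test = [apply_normalization(c, stats) for c in test_clouds]

    n_points = model_config.n_points
    # Fixed-seed, augmentation-free sampling of the evaluation clouds.
    test_fixed = [sample_points(c, n_points, seed=seed + 10_000 + i)
                  for i, c in enumerate(norm_test)]

    model = BioS2Net(model_config, seed=seed)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate,
                     betas=train_config.betas)
    history = TrainingHistory()
    root_rng = np.random.default_rng(seed)

    n_train = len(norm_train)
    for epoch in range(1, train_config.epochs + 1):
        order = root_rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, train_config.batch_size):
            batch_idx = order[start:start + train_config.batch_size]
            batch = []
            for i in batch_idx:
                sampled = sample_points(
                    norm_train[i], n_points,
                    seed=int(root_rng.integers(2 ** 31)))
                batch.append(augment(sampled, train_config.augmentation,
                                     root_rng))
            x = _batch_tensor(batch)
            out = model(x)
            loss = combined_loss(out["main_logits"], out["struct_logits"],
                                 out["temporal_logits"], y_train[batch_idx],
                                 model_config.loss_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        preds = _predict(model, test_fixed)
        main_pairs = list(zip(y_test, preds["main_logits"]))
        simple, mean_class = evaluate(main_pairs)
        head_acc = {}
        for key, p in preds.items():
            head_acc[key] = evaluate(list(zip(y_test, p)))[1]
        history.append(EpochRecord(epoch, float(np.mean(epoch_losses)),
                                   simple, mean_class, head_acc))
    fitted = FittedModel(model, stats, classes, model_config)
    return fitted, history


# -- embedding export ------------------------------------------------------

def extract_global_features(fitted: FittedModel, clouds: list[PointCloud],
                            seed: int = 0,
                            batch_size: int = 64) -> np.ndarray:
    """Global feature vectors (the classifier-head input), one row per protein.

    Clouds must already be normalized with the fitted statistics; sampling is
    fixed-seed and augmentation-free, so repeated extraction is identical.
    """
    n_points = fitted.model_config.n_points
    sampled = [sample_points(c, n_points, seed=seed + i)
               for i, c in enumerate(clouds)]
    fitted.model.set_training(False)
    rows = []
    for i in range(0, len(sampled), batch_size):
        out = fitted.model(_batch_tensor(sampled[i:i + batch_size]))
        rows.append(out["global_vector"].data.copy())
    fitted.model.set_training(True)
    return np.concatenate(rows, axis=0)


def write_feature_table(path, identifiers: list[str], labels: list[str],
                        matrix: np.ndarray) -> None:
    dim = matrix.shape[1]
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(f"f{i}" for i in range(dim)) + "\n")
        for sid, label, row in zip(identifiers, labels, matrix):
            fh.write(f"{sid}\t{label}\t"
                     + "\t".join(f"{v:.6f}" for v in row) + "\n")


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(path, fitted: FittedModel) -> None:
    """Versioned archive: config + normalization stats + flat weight list."""
    cfg = fitted.model_config
    meta = {
        "format_version": 1,
        "classes": fitted.classes,
        "global_scale": fitted.stats.global_scale,
        "b_factor_range": list(fitted.stats.b_factor_range),
        "model_config": {
            **{k: getattr(cfg, k) for k in (
                "n_classes", "n_points", "sequence_on", "seq_n_modules",
                "seq_filters_per_branch", "structure_on", "temporal_on",
                "temporal_n_modules", "temporal_filters_per_branch",
                "temporal_dilation")},
            "seq_kernels": list(cfg.seq_kernels),
            "temporal_kernels": list(cfg.temporal_kernels),
            "head_widths": list(cfg.head_widths),
            "loss_weights": list(cfg.loss_weights),
            "sa_layers": [
                {"n_centroids": l.n_centroids, "n_neighbors": l.n_neighbors,
                 "mlp_widths": list(l.mlp_widths),
                 "last_layer_global": l.last_layer_global}
                for l in cfg.sa_layers],
        },
    }
    params = fitted.model.parameters()
    buffers = fitted.model.buffers()
    arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(buffers)})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> FittedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        arrays = {k: archive[k] for k in archive.files if k != "meta"}
    mc = meta["model_config"]
    config = ModelConfig(
        n_classes=mc["n_classes"], n_points=mc["n_points"],
        sequence_on=mc["sequence_on"], seq_n_modules=mc["seq_n_modules"],
        seq_filters_per_branch=mc["seq_filters_per_branch"],
        seq_kernels=tuple(mc["seq_kernels"]),
        structure_on=mc["structure_on"],
        sa_layers=tuple(SALayerConfig(
            l["n_centroids"], l["n_neighbors"], tuple(l["mlp_widths"]),
            l["last_layer_global"]) for l in mc["sa_layers"]),
        temporal_on=mc["temporal_on"],
        temporal_n_modules=mc["temporal_n_modules"],
        temporal_filters_per_branch=mc["temporal_filters_per_branch"],
        temporal_kernels=tuple(mc["temporal_kernels"]),
        temporal_dilation=mc["temporal_dilation"],
        head_widths=tuple(mc["head_widths"]),
        loss_weights=tuple(mc["loss_weights"]),
    )
    model = BioS2Net(config, seed=0)
    for i, p in enumerate(model.parameters()):
        p.data[...] = arrays[f"param_{i}"]
    for i, b in enumerate(model.buffers()):
        b[...] = arrays[f"buffer_{i}"]
    stats = NormalizationStats(meta["global_scale"],
                               tuple(meta["b_factor_range"]))
    return FittedModel(model, stats, meta["classes"], config)
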