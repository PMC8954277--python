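"""The hybrid sequence/structure network and its configuration.

Four components operate on a fixed-size, sequence-ordered 53-feature point
cloud:

1. *Sequence extractor* — five stacked 1-D inception modules (kernels
   1/3/5/7) convolving along atom order; its per-point output is concatenated
   back onto the raw 53 features.
2. *Structure extractor* — three PointNet++-style set-abstraction levels
   (farthest-point sampling → k-nearest-neighbor grouping → shared per-point
   MLP on centroid-relative coordinates → per-region max pool). The last
   level has a single centroid, yielding one global structure vector
   (1024-dimensional in the default configuration).
3. *Temporal network* — takes the first-level centroids re-sorted into
   sequence order, each carrying raw + sequence-extractor + learned
   structural features, through six dilated (rate 3) inception modules each
   followed by length-2 max pooling, ending in global average pooling.
4. *Fusion head* — concatenates the structure and temporal vectors into the
   global feature vector and classifies it with a dense network. Auxiliary
   classification heads on the structure and temporal vectors stabilize
   training; their losses are combined with weights 0.5 (main), 0.35
   (structure), 0.15 (temporal).

Ablation switches remove a component's features from every downstream
concatenation and drop its auxiliary head (remaining loss weights are
renormalized); slots are omitted, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    BatchNorm,
    Dense,
    Inception1d,
    Module,
    PointwiseMLP,
    max_pool2,
)

N_INPUT_FEATURES = 53


class ConfigError(ValueError):
    """Raised for inconsistent model configurations."""


@dataclass
class SALayerConfig:
    n_centroids: int
    n_neighbors: int | None  # None → group every point (global layer)
    mlp_widths: tuple[int, ...]
    last_layer_global: bool = False


@dataclass
class ModelConfig:
    n_classes: int
    n_points: int = 1024
    # sequence extractor
    sequence_on: bool = True
    seq_n_modules: int = 5
    seq_filters_per_branch: int = 16
    seq_kernels: tuple[int, ...] = (1, 3, 5, 7)
    # structure extractor
    structure_on: bool = True
    sa_layers: tuple[SALayerConfig, ...] = (
        SALayerConfig(512, 32, (64, 64, 128)),
        SALayerConfig(128, 32, (128, 128, 256)),
        SALayerConfig(1, None, (256, 512, 1024), last_layer_global=True),
    )
    # temporal network
    temporal_on: bool = True
    temporal_n_modules: int = 6
    temporal_filters_per_branch: int = 16
    temporal_kernels: tuple[int, ...] = (1, 3, 5, 7)
    temporal_dilation: int = 3
    # fusion head
    head_widths: tuple[int, ...] = (512, 256)
    loss_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if not (self.structure_on or self.temporal_on):
            raise ConfigError(
                "both structure and temporal components disabled: "
                "no feature vector would reach the classifier")
        if len(self.sa_layers) != 3:
            raise ConfigError("exactly three set-abstraction layers required")
        if self.sa_layers[-1].n_centroids != 1:
            raise ConfigError("last set-abstraction layer must have one centroid")
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ConfigError("loss weights must sum to 1")
        m = self.sa_layers[0].n_centroids
        if self.temporal_on and m % (2 ** self.temporal_n_modules) != 0:
            raise ConfigError(
                "temporal network needs the first-level centroid count to be "
                f"divisible by 2^{self.temporal_n_modules}")
        prev = self.n_points
        for i, layer in enumerate(self.sa_layers):
            if layer.n_centroids > prev:
                raise ConfigError(
                    f"set-abstraction level {i + 1}: {layer.n_centroids} "
                    f"centroids exceed the {prev} available points")
            if layer.n_neighbors is not None and layer.n_neighbors > prev:
                raise ConfigError(
                    f"set-abstraction level {i + 1}: neighborhood size "
                    f"{layer.n_neighbors} exceeds the {prev} available points")
            prev = layer.n_centroids

    @classmethod
    def default(cls, n_classes: int, n_points: int = 1024,
                **overrides) -> "ModelConfig":
        cfg = cls(n_classes=n_classes, n_points=n_points, **overrides)
        cfg.validate()
        return cfg

    @classmethod
    def reduced(cls, n_classes: int, n_points: int = 256,
                **overrides) -> "ModelConfig":
        """Narrow CPU-scale configuration with the same topology."""
        kwargs = dict(
            n_classes=n_classes,
            n_points=n_points,
            seq_filters_per_branch=8,
            sa_layers=(
                SALayerConfig(64, 16, (32, 32, 64)),
                SALayerConfig(16, 8, (64, 64, 128)),
                SALayerConfig(1, None, (128, 128, 256),
                              last_layer_global=True),
            ),
            temporal_filters_per_branch=8,
            head_widths=(128, 64),
        )
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


# -- geometric primitives --------------------------------------------------

def farthest_point_sample(coords: np.ndarray, m: int) -> np.ndarray:
    """Greedy farthest-point sampling starting from index 0.

    Deterministic: each step adds the point maximizing the minimum distance
    to the chosen set, ties broken by lowest index.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if m > n:
        raise ValueError(f"cannot sample {m} centroids from {n} points")
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = 0
    min_d = np.linalg.norm(coords - coords[0], axis=1)
    for step in range(1, m):
        nxt = int(np.argmax(min_d))  # first occurrence → lowest index on ties
        chosen[step] = nxt
        min_d = np.minimum(min_d, np.linalg.norm(coords - coords[nxt], axis=1))
    return chosen


def group_neighbors(coords: np.ndarray, centroid_indices: np.ndarray,
                    k: int) -> np.ndarray:
    """k nearest points (the centroid itself included) for each centroid.

    Distance ties are broken by lowest point index.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"cannot group {k} neighbors from {n} points")
    diffs = coords[centroid_indices][:, None, :] - coords[None, :, :]
    d = np.einsum("ijk,ijk->ij", diffs, diffs)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


# -- modules ---------------------------------------------------------------

class SequenceExtractor(Module):
    """Stack of 1-D inception modules convolving along the atom-order axis."""

    def __init__(self, c_in: int, n_modules: int, filters_per_branch: int,
                 kernels: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.blocks = []
        prev = c_in
        for _ in range(n_modules):
            block = Inception1d(prev, filters_per_branch, rng, kernels)
            self.blocks.append(block)
            prev = block.c_out
        self.c_out = prev

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


@dataclass
class SetAbstractionOutput:
    centroid_coords: np.ndarray        # (B, S, 3)
    centroid_features: Tensor          # (B, S, F)
    centroid_source_indices: np.ndarray  # (B, S) indices into the level input


class SetAbstraction(Module):
    """One sampling → grouping → shared-MLP → max-pool level."""

    def __init__(self, c_in_features: int, config: SALayerConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.mlp = PointwiseMLP(3 + c_in_features, list(config.mlp_widths), rng)
        self.c_out = self.mlp.c_out

    def forward(self, coords: np.ndarray, feats: Tensor) -> SetAbstractionOutput:
        cfg = self.config
        B, n = coords.shape[:2]
        idx = np.stack([farthest_point_sample(coords[b], cfg.n_centroids)
                        for b in range(B)])
        k = n if cfg.n_neighbors is None else cfg.n_neighbors
        group_idx = np.stack([group_neighbors(coords[b], idx[b], k)
                              for b in range(B)])
        bidx = np.arange(B)[:, None]
        centroid_coords = coords[bidx, idx]                      # (B, S, 3)
        member_coords = coords[bidx[:, :, None], group_idx]      # (B, S, K, 3)
        local = member_coords - centroid_coords[:, :, None, :]
        member_feats = ag.gather(feats, group_idx)               # (B, S, K, F)
        region = ag.concat(
            [Tensor(local.astype(feats.data.dtype)), member_feats], axis=-1)
        pooled = ag.max_(self.mlp(region), axis=2)               # (B, S, F')
        return SetAbstractionOutput(centroid_coords, pooled, idx)


class StructureExtractor(Module):
    """Three-level set-abstraction hierarchy ending in one global centroid."""

    def __init__(self, c_in_features: int, layers: tuple[SALayerConfig, ...],
                 rng: np.random.Generator):
        super().__init__()
        self.levels = []
        prev = c_in_features
        for layer_cfg in layers:
            level = SetAbstraction(prev, layer_cfg, rng)
            self.levels.append(level)
            prev = level.c_out
        self.c_out = prev

    def forward(self, coords: np.ndarray,
                feats: Tensor) -> tuple[SetAbstractionOutput, Tensor]:
        sa1 = self.levels[0](coords, feats)
        out = sa1
        for level in self.levels[1:]:
            out = level(out.centroid_coords, out.centroid_features)
        global_vector = ag.reshape(out.centroid_features,
                                   (out.centroid_features.shape[0], self.c_out))
        return sa1, global_vector


class TemporalNetwork(Module):
    """Dilated inception stack over sequence-ordered centroids."""

    def __init__(self, c_in: int, n_modules: int, filters_per_branch: int,
                 kernels: tuple[int, ...], dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        self.blocks = []
        prev = c_in
        for _ in range(n_modules):
            block = Inception1d(prev, filters_per_branch, rng, kernels,
                                dilation)
            self.blocks.append(block)
            prev = block.c_out
        self.c_out = prev
        self.rows_before_gap: int | None = None

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = max_pool2(block(x))
        self.rows_before_gap = x.shape[1]
        return ag.mean_(x, axis=1)


class ClassifierHead(Module):
    def __init__(self, c_in: int, widths: tuple[int, ...], n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden = []
        prev = c_in
        for w in widths:
            self.hidden.append(Dense(prev, w, rng))
            self.hidden.append(BatchNorm(w))
            prev = w
        self.logits = Dense(prev, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        for i in range(0, len(self.hidden), 2):
            x = ag.relu(self.hidden[i + 1](self.hidden[i](x)))
        return self.logits(x)


class BioS2Net(Module):
    """Full architecture; ``forward`` returns logits, vectors and diagnostics."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)

        feat_dim = N_INPUT_FEATURES
        if config.sequence_on:
            self.seq = SequenceExtractor(
                N_INPUT_FEATURES, config.seq_n_modules,
                config.seq_filters_per_branch, config.seq_kernels, rng)
            feat_dim += self.seq.c_out
        self.feat_dim = feat_dim

        if config.structure_on:
            self.struct = StructureExtractor(feat_dim, config.sa_layers, rng)
            self.struct_head = Dense(self.struct.c_out, config.n_classes, rng)

        fused_dim = self.struct.c_out if config.structure_on else 0
        if config.temporal_on:
            t_in = feat_dim
            if config.structure_on:
                t_in += self.struct.levels[0].c_out
            self.temporal = TemporalNetwork(
                t_in, config.temporal_n_modules,
                config.temporal_filters_per_branch, config.temporal_kernels,
                config.temporal_dilation, rng)
            self.temporal_head = Dense(self.temporal.c_out, config.n_classes,
                                       rng)
            fused_dim += self.temporal.c_out
        self.fused_dim = fused_dim
        self.head = ClassifierHead(fused_dim, config.head_widths,
                                   config.n_classes, rng)

    # -----------------------------------------------------------------
    def forward(self, x: Tensor) -> dict:
        """Run the network on a batch of clouds, shape (B, n_points, 53)."""
        cfg = self.config
        if x.ndim != 3 or x.shape[2] != N_INPUT_FEATURES:
            raise ValueError(
                f"expected input of shape (B, N, {N_INPUT_FEATURES}), "
                f"got {x.shape}")
        coords = np.ascontiguousarray(x.data[:, :, :3], dtype=np.float64)

        feats = x
        if cfg.sequence_on:
            feats = ag.concat([x, self.seq(x)], axis=-1)

        out: dict = {"struct_logits": None, "temporal_logits": None}
        vectors: list[Tensor] = []
        sa1 = None
        if cfg.structure_on:
            sa1, global_vector = self.struct(coords, feats)
            out["struct_vector"] = global_vector
            out["struct_logits"] = self.struct_head(global_vector)
            out["sa1"] = sa1
            vectors.append(global_vector)

        if cfg.temporal_on:
            if sa1 is not None:
                src_idx = sa1.centroid_source_indices
                order = np.argsort(src_idx, axis=1, kind="stable")
                sorted_idx = np.take_along_axis(src_idx, order, axis=1)
                t_feats = ag.concat(
                    [ag.gather(feats, sorted_idx),
                     ag.gather(sa1.centroid_features, order)], axis=-1)
            else:
                m = cfg.sa_layers[0].n_centroids
                sorted_idx = np.stack([
                    np.sort(farthest_point_sample(coords[b], m))
                    for b in range(coords.shape[0])])
                t_feats = ag.gather(feats, sorted_idx)
            if np.any(np.diff(sorted_idx, axis=1) < 0):
                raise RuntimeError(
                    "temporal centroids are not in ascending sequence order")
            out["temporal_source_indices"] = sorted_idx
            temporal_vector = self.temporal(t_feats)
            out["temporal_vector"] = temporal_vector
            out["temporal_logits"] = self.temporal_head(temporal_vector)
            out["temporal_rows_before_gap"] = self.temporal.rows_before_gap
            vectors.append(temporal_vector)

        fused = vectors[0] if len(vectors) == 1 else ag.concat(vectors, -1)
        out["global_vector"] = fused
        out["main_logits"] = self.head(fused)
        out["probabilities"] = ag.softmax(out["main_logits"].data)
        return out
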