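"""Fixed-size point sampling and train-time cloud augmentation.

Sampling never shuffles: when a cloud has more atoms than the network input
size a uniform random subset is drawn and then re-sorted into original atom
order; smaller clouds are padded by cyclic repetition of their rows. This
preserves the sequence semantics the order-aware layers rely on.

Augmentation touches only the coordinate columns: a random proper rotation
(Z·Y·X Euler composition, angles uniform on [0, 2π)), uniform scaling,
uniform translation, and clipped Gaussian per-point jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cloud import COORD_COLS, PointCloud


@dataclass
class AugmentationConfig:
    rotation: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range: float = 0.1
    jitter_sigma: float = 0.005
    jitter_clip: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if lo > hi:
            raise ValueError("scale_range lower bound exceeds upper bound")
        if not (self.jitter_clip >= self.jitter_sigma >= 0):
            raise ValueError("need jitter_clip >= jitter_sigma >= 0")


def sample_points(cloud: PointCloud, n_points: int, seed: int) -> PointCloud:
    """Reduce (or pad) a cloud to exactly ``n_points`` rows in atom order."""
    if cloud.n_points == 0:
        raise ValueError("cannot sample from an empty cloud")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    n = cloud.n_points
    if n >= n_points:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=n_points, replace=False))
    else:
        idx = np.arange(n_points) % n  # cyclic repetition, order preserved
    return replace(cloud, points=cloud.points[idx])


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """R_z(gamma) @ R_y(beta) @ R_x(alpha)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment(cloud: PointCloud, config: AugmentationConfig,
            rng: np.random.Generator) -> PointCloud:
    """Apply one random rotation/scale/translation/jitter draw to the coordinates."""
    points = cloud.points.copy()
    coords = points[:, COORD_COLS]
    if config.rotation:
        angles = rng.uniform(0.0, 2.0 * np.pi, size=3)
        coords = coords @ rotation_matrix(*angles).T
    scale = rng.uniform(*config.scale_range)
    coords = coords * scale
    if config.translation_range > 0:
        coords = coords + rng.uniform(-config.translation_range,
                                      config.translation_range, size=3)
    if config.jitter_sigma > 0:
        jitter = rng.normal(0.0, config.jitter_sigma, size=coords.shape)
        coords = coords + np.clip(jitter, -config.jitter_clip, config.jitter_clip)
    points[:, COORD_COLS] = coords
    return replace(cloud, points=points)
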