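"""Per-atom featurization and dataset-level coordinate/B-factor normalization.

Every retained heavy atom becomes one 53-feature row (see :mod:`.cloud`).
Residue-level quantities — secondary structure, accessibility, amino-acid
identity, physicochemical scales, PSSM row — are inherited by each atom of
the residue. Raw PSSM log-odds are squashed to (0, 1) with the elementwise
logistic 1/(1 + exp(-score)).

Coordinate normalization is fit on the training set only: each protein is
centered at its own coordinate centroid, the radii of all training atoms are
pooled, and every protein is then divided by the single 95th-percentile
radius, so roughly 95% of training atoms land inside the unit sphere while
between-protein size ratios are preserved exactly. B factors are min-max
scaled by the pooled training range and clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import constants
from .asa import compute_accessible_area, relative_accessibility
from .cloud import (
    AA_ONEHOT_COLS,
    ASA_COL,
    B_FACTOR_COL,
    CHARGE_COL,
    COORD_COLS,
    HELIX_COL,
    N_FEATURES,
    NTERM_COL,
    OCCUPANCY_COL,
    PSSM_COLS,
    SHEET_COL,
    PointCloud,
)
from .secondary import SecondaryStructureAnnotation, assign_secondary_structure
from .structure_io import PSSM, ProteinStructure


@dataclass(frozen=True)
class NormalizationStats:
    """Training-set statistics shared by every protein in a run."""

    global_scale: float          # 95th-percentile centered-atom radius, Å
    b_factor_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.global_scale > 0:
            raise ValueError("global_scale must be positive")


def annotate(structure: ProteinStructure,
             asa_points: int = 960) -> SecondaryStructureAnnotation:
    """Secondary structure plus per-residue ASA from the built-in assigners."""
    ann = assign_secondary_structure(structure)
    ann.asa = compute_accessible_area(structure, n_points=asa_points)
    return ann


def featurize(structure: ProteinStructure, pssm: PSSM,
              annotation: SecondaryStructureAnnotation,
              label: str | None = None) -> PointCloud:
    """Build the raw (un-normalized) 53-column point cloud for one protein."""
    L = structure.length
    if pssm.scores.shape[0] != L:
        raise ValueError(
            f"PSSM rows ({pssm.scores.shape[0]}) != sequence length ({L})")
    if len(annotation) != L:
        raise ValueError(
            f"annotation length ({len(annotation)}) != sequence length ({L})")
    if annotation.asa is None:
        raise ValueError("annotation lacks accessible surface areas")

    rel_asa = relative_accessibility(structure, annotation.asa)
    pssm_features = 1.0 / (1.0 + np.exp(-pssm.scores))

    n = len(structure.atoms)
    points = np.zeros((n, N_FEATURES))
    if structure.unknown_residues:
        warnings.warn(
            f"{structure.identifier or 'structure'}: "
            f"{len(structure.unknown_residues)} unknown residue(s); "
            "one-hot and physicochemical features zeroed", stacklevel=2)
    for i, atom in enumerate(structure.atoms):
        r = atom.residue_ordinal - 1
        aa = structure.sequence[r]
        row = points[i]
        row[COORD_COLS] = atom.coords
        row[B_FACTOR_COL] = atom.b_factor
        row[OCCUPANCY_COL] = atom.occupancy
        row[NTERM_COL] = atom.residue_ordinal / L
        lbl = annotation.labels[r]
        row[HELIX_COL] = 1.0 if lbl == "helix" else 0.0
        row[SHEET_COL] = 1.0 if lbl == "sheet" else 0.0
        row[ASA_COL] = rel_asa[r]
        if aa in constants.AA_INDEX:
            row[AA_ONEHOT_COLS.start + constants.AA_INDEX[aa]] = 1.0
            row[CHARGE_COL] = constants.CHARGE[aa]
            row[CHARGE_COL + 1] = constants.POLARITY[aa]
            row[CHARGE_COL + 2] = constants.POLARIZABILITY[aa]
            row[CHARGE_COL + 3] = constants.HYDROPHOBICITY[aa]
        row[PSSM_COLS] = pssm_features[r]
    return PointCloud(points, source_id=structure.identifier, label=label)


def _centered_radii(cloud: PointCloud) -> np.ndarray:
    coords = cloud.coords
    return np.linalg.norm(coords - coords.mean(axis=0), axis=1)


def fit_normalization(training_clouds: list[PointCloud]) -> NormalizationStats:
    """Pool centered-atom radii and B factors over the training clouds."""
    if not training_clouds:
        raise ValueError("cannot fit normalization on an empty training set")
    radii = np.concatenate([_centered_radii(c) for c in training_clouds])
    scale = float(np.percentile(radii, 95.0))  # linear interpolation
    if scale <= 0:
        raise ValueError("degenerate training set: 95th-percentile radius is 0")
    b = np.concatenate([c.points[:, B_FACTOR_COL] for c in training_clouds])
    return NormalizationStats(scale, (float(b.min()), float(b.max())))


def apply_normalization(cloud: PointCloud, stats: NormalizationStats) -> PointCloud:
    """Center, rescale coordinates by the shared scale, min-max the B factor."""
    points = cloud.points.copy()
    coords = points[:, COORD_COLS]
    points[:, COORD_COLS] = (coords - coords.mean(axis=0)) / stats.global_scale
    lo, hi = stats.b_factor_range
    span = hi - lo
    if span > 0:
        points[:, B_FACTOR_COL] = np.clip(
            (points[:, B_FACTOR_COL] - lo) / span, 0.0, 1.0)
    else:
        points[:, B_FACTOR_COL] = 0.0
    return replace(cloud, points=points, normalized=True)
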