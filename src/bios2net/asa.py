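"""Shrake–Rupley solvent-accessible surface area.

Each atom is inflated by the 1.4 Å water-probe radius and covered with a
quasi-uniform golden-spiral point set; the accessible fraction is the share
of points not inside any other atom's probe-inflated sphere. Residue ASA is
the sum over its atoms; relative accessibility divides by the residue type's
theoretical maximum ASA and clips at 1.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_MAX_ASA, MAX_ASA, PROBE_RADIUS, VDW_RADII
from .structure_io import ProteinStructure


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (Fibonacci / golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_asa(coords: np.ndarray, radii: np.ndarray, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²) for probe-inflated spheres."""
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64) + PROBE_RADIUS
    n_atoms = coords.shape[0]
    unit = sphere_points(n_points)
    areas = np.empty(n_atoms)
    # Pairwise distances once, to restrict occlusion tests to true neighbors.
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n_atoms):
        neighbor_mask = d2[i] < (radii[i] + radii) ** 2
        neighbor_mask[i] = False
        nbrs = np.flatnonzero(neighbor_mask)
        if nbrs.size == 0:
            areas[i] = 4.0 * np.pi * radii[i] ** 2
            continue
        pts = coords[i] + radii[i] * unit
        dist2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(-1)
        buried = (dist2 < (radii[nbrs] ** 2)[None, :]).any(axis=1)
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * (1.0 - buried.mean())
    return areas


def compute_accessible_area(structure: ProteinStructure,
                            n_points: int = 960) -> np.ndarray:
    """Absolute per-residue ASA (Å²), indexed by residue ordinal - 1."""
    coords = structure.coords
    radii = np.array([VDW_RADII[a.element] for a in structure.atoms])
    per_atom = atom_asa(coords, radii, n_points)
    out = np.zeros(structure.length)
    for atom, area in zip(structure.atoms, per_atom):
        out[atom.residue_ordinal - 1] += area
    return out


def relative_accessibility(structure: ProteinStructure,
                           residue_asa: np.ndarray) -> np.ndarray:
    """Residue ASA normalized by the per-type maximum, clipped to [0, 1]."""
    rel = np.empty_like(residue_asa)
    for i, aa in enumerate(structure.sequence):
        rel[i] = residue_asa[i] / MAX_ASA.get(aa, DEFAULT_MAX_ASA)
    return np.clip(rel, 0.0, 1.0)
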