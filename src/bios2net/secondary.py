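"""Secondary-structure assignment and DSSP-output import.

The built-in assigner is a simplified Kabsch–Sander procedure: backbone
amide hydrogens are reconstructed from peptide geometry, hydrogen bonds are
detected with the classic electrostatic energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332   [kcal/mol]

using the -0.5 kcal/mol cutoff, and the eight DSSP classes are collapsed to
the two indicator groups the featurizer needs: helix (3-10/alpha/pi, DSSP
G/H/I) and sheet (beta bridge/ladder, DSSP E/B). Everything else is "other".

A precomputed classic-format DSSP output file can be imported instead, in
which case only the two-group mapping is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

HBOND_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0

HELIX_CODES = frozenset("GHI")
SHEET_CODES = frozenset("EB")


@dataclass
class SecondaryStructureAnnotation:
    """Per-residue two-group labels plus accessible surface area (Å²)."""

    labels: list[str]  # each in {"helix", "sheet", "other"}
    asa: np.ndarray | None = None  # absolute per-residue ASA, Å²

    def __len__(self) -> int:
        return len(self.labels)


def backbone_coordinates(structure: ProteinStructure) -> dict[str, np.ndarray]:
    """Per-residue N/CA/C/O coordinates; NaN where a backbone atom is absent."""
    L = structure.length
    out = {name: np.full((L, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for atom in structure.atoms:
        if atom.name in out and np.isnan(out[atom.name][atom.residue_ordinal - 1]).all():
            out[atom.name][atom.residue_ordinal - 1] = atom.coords
    return out


def _amide_hydrogens(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Reconstruct amide H positions: 1 Å from N along the previous C=O direction."""
    n = bb["N"]
    h = np.full_like(n, np.nan)
    c_prev = bb["C"][:-1]
    o_prev = bb["O"][:-1]
    d = c_prev - o_prev
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        h[1:] = n[1:] + d / norm
    return h


def hydrogen_bond_energy(bb: dict[str, np.ndarray]) -> np.ndarray:
    """L×L matrix: E[i, j] is the CO(i)→NH(j) Kabsch–Sander energy (kcal/mol).

    Entries involving missing atoms, the chain termini without a
    reconstructable hydrogen, or |i - j| < 2 are +inf (no bond).
    """
    L = bb["N"].shape[0]
    h = _amide_hydrogens(bb)
    c, o, n = bb["C"], bb["O"], bb["N"]

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        e = _Q1Q2_F * (1.0 / dist(o, n) + 1.0 / dist(c, h)
                       - 1.0 / dist(o, h) - 1.0 / dist(c, n))
    e = np.where(np.isfinite(e), e, np.inf)
    idx = np.arange(L)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    e[near] = np.inf
    return e


def _dssp_codes_from_geometry(structure: ProteinStructure) -> str:
    bb = backbone_coordinates(structure)
    L = structure.length
    missing = np.zeros(L, dtype=bool)
    for name in ("N", "CA", "C", "O"):
        missing |= np.isnan(bb[name]).any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} residue(s) lack backbone atoms; labeled 'other'",
            stacklevel=3,
        )
    e = hydrogen_bond_energy(bb)
    hbond = e < HBOND_CUTOFF

    codes = np.array(["-"] * L)

    # Helices: two consecutive n-turns (n = 3, 4, 5) mark residues i+1..i+n.
    for n_turn, code in ((5, "I"), (3, "G"), (4, "H")):
        turn = np.zeros(L, dtype=bool)
        for i in range(L - n_turn):
            if hbond[i, i + n_turn]:
                turn[i] = True
        for i in range(L - 1):
            if turn[i] and turn[i + 1]:
                codes[i + 1:i + 1 + n_turn] = code

    # Beta bridges: Kabsch–Sander parallel/antiparallel patterns.
    bridge = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(1, L - 1):
            if abs(i - j) < 3:
                continue
            parallel = (hbond[i - 1, j] and hbond[j, i + 1]) or \
                       (hbond[j - 1, i] and hbond[i, j + 1])
            anti = (hbond[i, j] and hbond[j, i]) or \
                   (hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            if parallel or anti:
                bridge[i] = bridge[j] = True
    for i in range(L):
        if bridge[i] and codes[i] == "-":
            codes[i] = "E"

    codes[missing] = "-"
    return "".join(codes)


def collapse_codes(codes: str) -> list[str]:
    """Map DSSP classes to the two-group labels (helix wins over sheet)."""
    out = []
    for c in codes:
        if c in HELIX_CODES:
            out.append("helix")
        elif c in SHEET_CODES:
            out.append("sheet")
        else:
            out.append("other")
    return out


def assign_secondary_structure(structure: ProteinStructure) -> SecondaryStructureAnnotation:
    """Assign helix/sheet/other labels from backbone geometry."""
    codes = _dssp_codes_from_geometry(structure)
    return SecondaryStructureAnnotation(collapse_codes(codes))


def read_dssp(dssp_text: str) -> SecondaryStructureAnnotation:
    """Import a classic DSSP output file and apply the two-group mapping.

    Reads the per-residue summary code (column 17) and the ACC field; chain
    break rows ('!') are skipped.
    """
    labels: list[str] = []
    asa: list[float] = []
    in_table = False
    for line in dssp_text.splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        if line[13] == "!":
            continue
        code = line[16]
        labels.append("helix" if code in HELIX_CODES
                      else "sheet" if code in SHEET_CODES else "other")
        try:
            asa.append(float(line[34:38]))
        except (ValueError, IndexError):
            asa.append(np.nan)
    if not labels:
        raise ValueError("no residue rows found in DSSP output")
    return SecondaryStructureAnnotation(labels, np.array(asa))
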