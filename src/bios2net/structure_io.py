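"""Readers for PDB structures and PSI-BLAST PSSM files.

Parsing rules for structures:

* only ``ATOM`` records are used (HETATM, waters, and all non-polymer records
  are skipped), and only from the first model of multi-model (NMR) files;
* hydrogens and any element outside {C, N, O, S} are dropped;
* for alternate locations, only the highest-occupancy altloc of each atom is
  kept (ties resolved in favour of the record that appears first in the file);
* surviving atoms keep their file order — downstream sequence-aware layers
  depend on it;
* multiple chains are concatenated in file order and residue ordinals continue
  cumulatively across chain breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import (  # noqa: F401  (re-exported: clouds are this module's file format)
    PointCloud,
    PointCloudError,
    read_point_cloud,
    write_point_cloud,
)
from .constants import AA_ORDER, ALLOWED_ELEMENTS, THREE_TO_ONE


class ParseError(ValueError):
    """Raised on malformed PDB or PSSM input."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray
    b_factor: float
    occupancy: float
    residue_ordinal: int  # 1-based index within the concatenated chain sequence
    residue_name: str
    chain_id: str
    altloc: str = " "
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)


@dataclass
class ProteinStructure:
    """Ordered heavy-atom list plus the derived one-letter sequence."""

    atoms: list[Atom]
    sequence: str
    identifier: str = ""
    unknown_residues: frozenset[int] = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=np.float64)


@dataclass
class PSSM:
    """L×20 raw PSI-BLAST log-odds scores in the fixed PSI-BLAST column order."""

    scores: np.ndarray
    column_order: str = AA_ORDER
    synthetic_zero: bool = False  # True for the zero matrix used when no PSSM exists

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ParseError(f"PSSM must be L×20, got {self.scores.shape}")


def _element_from_record(line: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        # Fall back on the atom-name columns: column 13 is blank for
        # single-letter elements, so the element letter sits at column 14.
        name = line[12:16]
        elem = name[:2].strip().lstrip("0123456789")
        if len(elem) == 2 and elem[0] in "HCNOS" and not name.startswith(elem):
            elem = elem[0]
        elem = elem[:1] if elem[:1] in "HCNOS" else elem
    return elem.capitalize()


def parse_structure(pdb_text: str, identifier: str = "") -> ProteinStructure:
    """Parse ATOM records from PDB-format text into a :class:`ProteinStructure`."""
    raw: list[tuple] = []  # (order, residue_key, altloc, occupancy, atom fields)
    model_seen = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            model_seen += 1
            if model_seen > 1:
                break
        elif rec == "ENDMDL":
            if model_seen >= 1:
                break
        elif rec == "ATOM  ":
            try:
                name = line[12:16]
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resseq = line[22:26].strip()
                icode = line[26]
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"malformed ATOM record at line {lineno}") from exc
            if resname == "HOH":
                continue
            element = _element_from_record(line)
            if element not in ALLOWED_ELEMENTS:
                continue
            raw.append((len(raw), (chain, resseq, icode), altloc, occ,
                        (element, (x, y, z), bfac, occ, resname, chain, name)))
    if not raw:
        raise ParseError("no usable ATOM records found")

    # Altloc resolution: among records sharing (residue, atom name), keep the
    # highest occupancy; ties go to the earliest record in the file.
    best: dict[tuple, tuple] = {}
    for entry in raw:
        order, reskey, altloc, occ, fields = entry
        key = (reskey, fields[6])  # residue + atom name
        prev = best.get(key)
        if prev is None or occ > prev[3]:
            best[key] = entry

    kept = sorted(best.values(), key=lambda e: e[0])

    # Residue ordinals in file order, cumulative across chains.
    atoms: list[Atom] = []
    sequence: list[str] = []
    unknown: set[int] = set()
    last_reskey = None
    ordinal = 0
    for order, reskey, altloc, occ, fields in kept:
        element, xyz, bfac, occ_f, resname, chain, name = fields
        if reskey != last_reskey:
            ordinal += 1
            last_reskey = reskey
            one = THREE_TO_ONE.get(resname, "X")
            sequence.append(one)
            if one == "X":
                unknown.add(ordinal)
        atoms.append(Atom(element, np.array(xyz), bfac,
                          min(max(occ_f, 0.0), 1.0), ordinal, resname, chain,
                          altloc, name.strip()))
    return ProteinStructure(atoms, "".join(sequence), identifier,
                            frozenset(unknown))


def zero_pssm(length: int) -> PSSM:
    """Zero score matrix used when no PSSM file exists for a structure."""
    return PSSM(np.zeros((length, 20)), synthetic_zero=True)


def read_pssm(pssm_text: str, expected_length: int) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM (the 20 log-odds columns).

    Rows are lines starting with a residue index and a one-letter amino acid,
    followed by at least 20 integer scores. The parse fails loudly on a
    malformed row or when the number of rows differs from ``expected_length``.
    """
    rows: list[list[int]] = []
    for lineno, line in enumerate(pssm_text.splitlines(), start=1):
        parts = line.split()
        if len(parts) < 22:
            continue
        if not (parts[0].isdigit() and len(parts[1]) == 1 and parts[1].isalpha()):
            continue
        try:
            scores = [int(v) for v in parts[2:22]]
        except ValueError as exc:
            raise ParseError(f"malformed PSSM row at line {lineno}") from exc
        rows.append(scores)
    if not rows:
        raise ParseError("no PSSM score rows found")
    if len(rows) != expected_length:
        raise ParseError(
            f"PSSM has {len(rows)} rows but the sequence has "
            f"{expected_length} residues"
        )
    return PSSM(np.array(rows, dtype=np.float64))
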