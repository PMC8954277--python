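"""Residue-level lookup tables and atomic constants.

All per-residue physicochemical scales are stored twice: ``*_RAW`` holds the
published values in their original units, and the module-level normalized
dictionaries hold the values rescaled once, at import time, to the ranges the
point-cloud feature contract requires ([0, 1] everywhere, charge in [-1, 1]).

Sources of the raw scales:

* charge — isoelectric points of the free amino acids (CRC Handbook).
* polarity — Grantham (1974) polarity scale.
* polarizability — Charton & Charton (1982).
* hydrophobicity — Kyte & Doolittle (1982).
* maximum accessible surface area — theoretical Gly-X-Gly values of
  Tien et al. (2013), used to turn absolute residue ASA into relative burial.
"""

from __future__ import annotations

# Fixed 20-letter ordering shared by the amino-acid one-hot block and the
# PSSM block: the PSI-BLAST column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Heavy-atom elements retained in protein point clouds.
ALLOWED_ELEMENTS = ("C", "N", "O", "S")

# van der Waals radii (Å) for solvent-accessibility calculations.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
PROBE_RADIUS = 1.4  # water probe, Å

ISOELECTRIC_POINT_RAW = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

POLARITY_RAW = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

POLARIZABILITY_RAW = {
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
}

HYDROPHOBICITY_RAW = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
# Fallback for residues outside the standard 20 (flagged unknown upstream).
DEFAULT_MAX_ASA = 200.0


def _minmax(table: dict[str, float], lo: float, hi: float) -> dict[str, float]:
    vmin = min(table.values())
    vmax = max(table.values())
    span = vmax - vmin
    return {k: lo + (hi - lo) * (v - vmin) / span for k, v in table.items()}


# Normalized scales used directly by the featurizer.
CHARGE = _minmax(ISOELECTRIC_POINT_RAW, -1.0, 1.0)
POLARITY = _minmax(POLARITY_RAW, 0.0, 1.0)
POLARIZABILITY = _minmax(POLARIZABILITY_RAW, 0.0, 1.0)
HYDROPHOBICITY = _minmax(HYDROPHOBICITY_RAW, 0.0, 1.0)
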