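"""The 53-column point-cloud container and its on-disk TSV format.

Each protein is an ordered table with one row per retained heavy atom and a
fixed 53-column layout::

    1-3    x, y, z             coordinates (Å raw; normalized units after scaling)
    4      b_factor            temperature factor
    5      occupancy
    6      nterm_distance      residue ordinal / sequence length
    7-8    is_helix, is_sheet  two-group secondary-structure indicators
    9      accessible_area     relative residue solvent accessibility
    10-29  aa_*                amino-acid one-hot (PSI-BLAST letter order)
    30-33  charge, polarity, polarizability, hydrophobicity
    34-53  pssm_*              squashed PSSM scores (PSI-BLAST letter order)

Row order always equals ATOM-record order of the source structure; nothing in
the pipeline may shuffle rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_ORDER

FEATURE_NAMES: tuple[str, ...] = (
    "x", "y", "z", "b_factor", "occupancy", "nterm_distance",
    "is_helix", "is_sheet", "accessible_area",
    *(f"aa_{a}" for a in AA_ORDER),
    "charge", "polarity", "polarizability", "hydrophobicity",
    *(f"pssm_{a}" for a in AA_ORDER),
)
N_FEATURES = len(FEATURE_NAMES)  # 53

# Column index blocks (0-based).
COORD_COLS = slice(0, 3)
B_FACTOR_COL = 3
OCCUPANCY_COL = 4
NTERM_COL = 5
HELIX_COL = 6
SHEET_COL = 7
ASA_COL = 8
AA_ONEHOT_COLS = slice(9, 29)
CHARGE_COL = 29
PSSM_COLS = slice(33, 53)


class PointCloudError(ValueError):
    """Raised for malformed point clouds or point-cloud files."""


@dataclass
class PointCloud:
    """Ordered N×53 feature table for one protein.

    ``normalized`` records whether coordinates and B factors have been put on
    the dataset scale; raw clouds carry Å coordinates and raw B factors, which
    are exempt from the [0, 1] range checks until normalization.
    """

    points: np.ndarray
    source_id: str = ""
    label: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != N_FEATURES:
            raise PointCloudError(
                f"point cloud must have exactly {N_FEATURES} columns, "
                f"got shape {self.points.shape}"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def coords(self) -> np.ndarray:
        return self.points[:, COORD_COLS]

    def validate(self) -> None:
        """Check the column-range invariants; raise PointCloudError on violation."""
        p = self.points
        if not np.isfinite(p).all():
            raise PointCloudError("non-finite feature values")
        unit_cols = [OCCUPANCY_COL, NTERM_COL, HELIX_COL, SHEET_COL, ASA_COL]
        blocks = p[:, unit_cols]
        if blocks.min(initial=0.0) < -1e-9 or blocks.max(initial=0.0) > 1 + 1e-9:
            raise PointCloudError("structural feature out of [0, 1]")
        onehot = p[:, AA_ONEHOT_COLS]
        sums = onehot.sum(axis=1)
        if not np.all((np.isclose(sums, 0) | np.isclose(sums, 1))):
            raise PointCloudError("amino-acid one-hot rows must sum to 0 or 1")
        if np.any(p[:, HELIX_COL] + p[:, SHEET_COL] > 1 + 1e-9):
            raise PointCloudError("residue flagged both helix and sheet")
        if np.abs(p[:, CHARGE_COL]).max(initial=0.0) > 1 + 1e-9:
            raise PointCloudError("charge out of [-1, 1]")
        phys = p[:, CHARGE_COL + 1:PSSM_COLS.start]
        pssm = p[:, PSSM_COLS]
        for name, block in (("physicochemical", phys), ("pssm", pssm)):
            if block.size and (block.min() < -1e-9 or block.max() > 1 + 1e-9):
                raise PointCloudError(f"{name} feature out of [0, 1]")
        if self.normalized:
            b = p[:, B_FACTOR_COL]
            if b.min(initial=0.0) < -1e-9 or b.max(initial=0.0) > 1 + 1e-9:
                raise PointCloudError("normalized B factor out of [0, 1]")


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud as TSV: comment metadata lines, a header row, one row per atom."""
    df = pd.DataFrame(cloud.points, columns=list(FEATURE_NAMES))
    with open(path, "w") as fh:
        fh.write(f"# source_id={cloud.source_id}\n")
        fh.write(f"# label={'' if cloud.label is None else cloud.label}\n")
        fh.write(f"# normalized={int(cloud.normalized)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_point_cloud(path) -> PointCloud:
    """Read a TSV written by :func:`write_point_cloud`.

    The header must name all 53 features in canonical order; the order is part
    of the format and a permuted or truncated header is a format error.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if tuple(df.columns) != FEATURE_NAMES:
        raise PointCloudError(
            "point-cloud file header does not match the canonical 53-feature "
            f"layout (got {len(df.columns)} columns)"
        )
    label = meta.get("label", "") or None
    return PointCloud(
        df.to_numpy(dtype=np.float64),
        source_id=meta.get("source_id", ""),
        label=label,
        normalized=bool(int(meta.get("normalized", "0"))),
    )
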