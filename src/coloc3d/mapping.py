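"""Placement of genomic features on a 3D genome model.

Each chromosome of the model is an ordered series of anchor points; two
successive anchors delimit a chromosomal region in space.  A feature is
represented by a single point: its genomic midpoint is located between the
bracketing anchors and its spatial position is obtained by linear
interpolation along that segment.  Positions outside the anchored range are
clamped to the terminal anchor so mapped points never leave the modelled
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MappingError
from .io import FeatureTable, Model3D


@dataclass
class CoordinateTable:
    """One 3D point per mapped feature.

    ``records`` has columns (feature_id, chromosome, anchor_bp, x, y, z);
    ``report`` lists features skipped because their chromosome is absent
    from the model.
    """

    records: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return self.records["feature_id"].tolist()

    def coords(self) -> np.ndarray:
        """(n, 3) float64 array of x,y,z in input order."""
        return self.records[["x", "y", "z"]].to_numpy(dtype=np.float64)


def feature_anchor_bp(start: int, end: int) -> int:
    """Genomic position representing a feature: floor of its midpoint."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return (start + end) // 2


def interpolate_coordinate(positions: np.ndarray, coords: np.ndarray,
                           bp: float | np.ndarray) -> np.ndarray:
    """Interpolate 3D coordinates for genomic position(s) along one
    chromosome path.

    ``positions`` is a strictly increasing (k,) array of anchor bp;
    ``coords`` the matching (k, 3) array.  Between anchors (b1, P1) and
    (b2, P2) the result is the affine combination (1-t)*P1 + t*P2 with
    t = (bp-b1)/(b2-b1); positions before the first or after the last
    anchor are clamped to the terminal anchor.  At an anchor bp the
    anchor's coordinates are returned exactly.
    """
    positions = np.asarray(positions)
    coords = np.asarray(coords, dtype=np.float64)
    if len(positions) < 2:
        raise MappingError("chromosome path needs >= 2 anchors")
    bp_arr = np.atleast_1d(np.asarray(bp, dtype=np.float64))
    seg = np.clip(np.searchsorted(positions, bp_arr, side="right") - 1,
                  0, len(positions) - 2)
    b1 = positions[seg].astype(np.float64)
    b2 = positions[seg + 1].astype(np.float64)
    t = np.clip((bp_arr - b1) / (b2 - b1), 0.0, 1.0)
    # (1-t)*P1 + t*P2 is exact at t=0 and t=1
    out = (1.0 - t)[:, None] * coords[seg] + t[:, None] * coords[seg + 1]
    if np.isscalar(bp) or np.ndim(bp) == 0:
        return out[0]
    return out


def map_features(model: Model3D, features: FeatureTable) -> CoordinateTable:
    """Assign one interpolated 3D point to every feature on a modelled
    chromosome.

    Features on chromosomes absent from the model are skipped and listed in
    the report; output order follows input order of the retained features.
    Raises :class:`MappingError` when no feature can be mapped.
    """
    modelled = set(model.chromosomes)
    df = features.records
    on_model = df["chromosome"].isin(modelled)
    skipped = df.loc[~on_model, "feature_id"].tolist()
    kept = df[on_model]
    if kept.empty:
        raise MappingError("no feature lies on a modelled chromosome")

    mid = ((kept["start"].to_numpy(np.int64) + kept["end"].to_numpy(np.int64)) // 2)
    xyz = np.empty((len(kept), 3), dtype=np.float64)
    pos_index = np.arange(len(kept))
    chrom_arr = kept["chromosome"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        sel = pos_index[chrom_arr == chrom]
        positions, coords = model.path(chrom)
        xyz[sel] = interpolate_coordinate(positions, coords, mid[sel])

    records = pd.DataFrame({
        "feature_id": kept["feature_id"].to_numpy(),
        "chromosome": chrom_arr,
        "anchor_bp": mid,
        "x": xyz[:, 0],
        "y": xyz[:, 1],
        "z": xyz[:, 2],
    })
    return CoordinateTable(
        records=records,
        report={
            "n_input": len(df),
            "n_mapped": len(records),
            "skipped_chromosome_missing": skipped,
        },
    )


def write_coordinates(coords: CoordinateTable, path: str | Path) -> None:
    coords.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_coordinates(path: str | Path) -> CoordinateTable:
    df = pd.read_csv(path, sep="\t",
                     dtype={"feature_id": str, "chromosome": str},
                     float_precision="round_trip")
    required = {"feature_id", "chromosome", "anchor_bp", "x", "y", "z"}
    if not required <= set(df.columns):
        raise MappingError(f"{path}: missing coordinate columns")
    df["feature_id"] = df["feature_id"].str.upper()
    return CoordinateTable(records=df)
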