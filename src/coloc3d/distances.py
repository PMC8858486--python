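"""All-pairs Euclidean distances and the background distance distribution.

Distances are stored in condensed form: for n features the n(n-1)/2
unordered pairs (i, j), i < j, are laid out row-major at index

    idx(i, j) = n*i - i*(i+1)/2 + (j - i - 1)

which is the canonical upper-triangle ordering also used by
``scipy.spatial.distance.pdist``, so external tools can address the vector
directly.  Computation is done in double precision, blocked over rows so
peak temporary memory is bounded by the block size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ModuleTooSmallError, ParameterError, UnknownFeatureError
from .io import GeneList
from .mapping import CoordinateTable


def condensed_index(i, j, n: int):
    """Condensed vector position of pair (i, j), i < j, for n items.

    Accepts scalars or equally-shaped integer arrays.
    """
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(i >= j):
        raise ValueError("condensed_index requires i < j")
    out = n * i - i * (i + 1) // 2 + (j - i - 1)
    return out if out.ndim else int(out)


@dataclass
class DistanceSet:
    """Condensed vector of all pairwise Euclidean distances.

    ``d`` has length n(n-1)/2; ``ids`` maps positions 0..n-1 to feature
    identifiers.
    """

    d: np.ndarray
    ids: list[str]
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = [str(g) for g in self.ids]
        self.id_index = {g: k for k, g in enumerate(self.ids)}
        n = len(self.ids)
        if len(self.d) != n * (n - 1) // 2:
            raise ValueError(
                f"condensed length {len(self.d)} != n(n-1)/2 for n={n}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.d)

    def sorted_values(self) -> np.ndarray:
        """Ascending copy of the distances, cached (used as KS reference)."""
        cached = getattr(self, "_sorted", None)
        if cached is None:
            cached = np.sort(self.d)
            self._sorted = cached
        return cached

    def median(self) -> float:
        s = self.sorted_values()
        m = len(s)
        return float(s[m // 2] if m % 2 else 0.5 * (s[m // 2 - 1] + s[m // 2]))


def pairwise_distances(coords: CoordinateTable | np.ndarray,
                       ids: list[str] | None = None,
                       block_size: int = 512) -> DistanceSet:
    """Compute the condensed vector of all pairwise Euclidean distances.

    ``coords`` is a :class:`CoordinateTable` or an (n, 3) array (then
    ``ids`` must be given).  ``block_size`` rows are processed per chunk;
    peak temporary memory is O(block_size * n).
    """
    if isinstance(coords, CoordinateTable):
        xyz = coords.coords()
        ids = coords.ids
    else:
        xyz = np.asarray(coords, dtype=np.float64)
        if ids is None:
            raise ParameterError("ids are required with a raw coordinate array")
    n = len(xyz)
    if n < 2:
        raise ParameterError(f"need >= 2 features, got {n}")
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")

    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    for a in range(0, n, block_size):
        b = min(a + block_size, n)
        # (b-a, n, 3) differences against every point; elementwise identical
        # to the naive per-pair formula
        diff = xyz[a:b, None, :] - xyz[None, :, :]
        block = np.sqrt(diff[..., 0] ** 2 + diff[..., 1] ** 2 + diff[..., 2] ** 2)
        for i in range(a, b):
            s = n * i - i * (i + 1) // 2
            out[s:s + n - i - 1] = block[i - a, i + 1:]
    return DistanceSet(d=out, ids=list(ids), report={"n": n, "block_size": block_size})


def get_distance(dset: DistanceSet, a: str, b: str) -> float:
    """Distance between two features by id; symmetric, zero on the diagonal."""
    a, b = str(a).upper(), str(b).upper()
    for g in (a, b):
        if g not in dset.id_index:
            raise UnknownFeatureError(g)
    i, j = dset.id_index[a], dset.id_index[b]
    if i == j:
        return 0.0
    if i > j:
        i, j = j, i
    return float(dset.d[condensed_index(i, j, dset.n)])


def subset_distances(dset: DistanceSet, genes: GeneList | list[str]
                     ) -> tuple[np.ndarray, dict]:
    """Distances among the matched members of a gene list.

    Returns the k(k-1)/2 pairwise distances for the k list members present
    in the index, and a report with the unmatched identifiers.  Raises
    :class:`ModuleTooSmallError` when fewer than two members match.
    """
    ids = list(genes.ids) if isinstance(genes, GeneList) else [str(g).upper() for g in genes]
    matched = [g for g in ids if g in dset.id_index]
    unmatched = [g for g in ids if g not in dset.id_index]
    if len(matched) < 2:
        raise ModuleTooSmallError(len(matched), unmatched)
    idx = np.sort(np.array([dset.id_index[g] for g in matched], dtype=np.int64))
    iu, ju = np.triu_indices(len(idx), k=1)
    ci = condensed_index(idx[iu], idx[ju], dset.n)
    return dset.d[ci], {"n_matched": len(matched), "unmatched": unmatched}


@dataclass
class DistanceDistribution:
    """Binned background distance distribution: equal-width density histogram
    plus the cumulative distribution evaluated at the bin edges."""

    bin_edges: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    source_count: int


def background_distribution(dset: DistanceSet | np.ndarray,
                            n_bins: int = 100) -> DistanceDistribution:
    """Histogram all distances into ``n_bins`` equal-width bins on
    [0, max distance]; density integrates to 1 and the CDF runs from 0 to 1
    across the edges."""
    if n_bins < 1:
        raise ParameterError(f"n_bins must be >= 1, got {n_bins}")
    values = dset.d if isinstance(dset, DistanceSet) else np.asarray(dset, dtype=float)
    if len(values) == 0:
        raise ParameterError("empty distance set")
    upper = float(values.max())
    if upper <= 0.0:
        upper = 1.0  # all-zero degenerate set still gets a well-formed axis
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, upper))
    total = counts.sum()
    width = edges[1] - edges[0]
    density = counts / (total * width)
    cdf = np.concatenate(([0.0], np.cumsum(counts) / total))
    return DistanceDistribution(bin_edges=edges, density=density, cdf=cdf,
                                source_count=int(len(values)))


# ---------------------------------------------------------------------------
# Persistence (Parquet condensed vector + id metadata)
# ---------------------------------------------------------------------------

_IDS_KEY = b"coloc3d.ids"


def write_distances(dset: DistanceSet, path: str | Path,
                    precision: str = "single") -> None:
    """Persist the condensed vector as a one-column Parquet table.

    ``precision`` is "single" (default; halves file size) or "double".
    Feature ids travel in the file metadata so the index round-trips.
    """
    import pyarrow as pa
    import pyarrow.parquet as pq

    if precision not in ("single", "double"):
        raise ParameterError(f"precision must be 'single' or 'double', got {precision!r}")
    values = dset.d.astype(np.float32 if precision == "single" else np.float64)
    table = pa.table({"distance": values})
    meta = {_IDS_KEY: json.dumps(dset.ids).encode(),
            b"coloc3d.precision": precision.encode()}
    table = table.replace_schema_metadata(meta)
    pq.write_table(table, str(path), compression="zstd")


def read_distances(path: str | Path) -> DistanceSet:
    import pyarrow.parquet as pq

    table = pq.read_table(str(path))
    meta = table.schema.metadata or {}
    if _IDS_KEY not in meta:
        raise ParameterError(f"{path}: not a coloc3d distance file (no id metadata)")
    ids = json.loads(meta[_IDS_KEY].decode())
    d = table.column("distance").to_numpy().astype(np.float64)
    return DistanceSet(d=d, ids=ids)
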