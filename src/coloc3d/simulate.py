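"""Synthetic 3D genome models with Rabl-like nuclear architecture.

The generator emulates the geometry of a budding-yeast interphase nucleus:
chromosomes live inside a sphere, centromeres cluster near one pole of the
nuclear envelope, and chromosome arms extend outward until the telomeres,
which end up near the envelope.  Each chromosome is built as two fixed-step
random walks leaving the centromere anchor, with step direction biased away
from the pole and reflection at the sphere so every anchor stays inside the
nucleus.  Anchor genomic spacings are drawn around a mean, so anchors are
not equidistant in bp — the background distance distribution then has the
variable-resolution character of experimentally derived models.  Genes are
tiled at fixed genomic intervals along every chromosome.

This is a geometric stand-in, not a polymer model: no excluded volume, no
chromatin persistence length, no nucleolus.  Its purpose is to provide
fully reproducible inputs for every pipeline stage, with or without planted
spatially clustered gene modules as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleModuleError, ParameterError
from .io import FeatureTable, GeneList, Model3D
from .mapping import CoordinateTable


def _default_lengths(n: int) -> list[int]:
    # deterministic spread over the 200 kb – 1.5 Mb range of yeast chromosomes
    return [int(v) for v in np.linspace(200_000, 1_500_000, n)]


@dataclass
class SimulationParams:
    """Parameters of the synthetic genome generator.

    Model-space units are arbitrary with the nucleus radius as the natural
    scale (default 1.0).  Defaults mimic a 16-chromosome yeast-like genome:
    chromosome lengths spread over 200–1500 kb, anchors every ~10 kb, genes
    tiled every 2 kb.
    """

    n_chromosomes: int = 16
    chromosome_lengths: list[int] | None = None
    anchor_spacing_mean: int = 10_000
    gene_spacing: int = 2_000
    gene_length: int = 1_000
    nucleus_radius: float = 1.0
    centromere_positions: list[int] | None = None
    centromere_cluster_sd: float = 0.1
    step_length: float = 0.05
    outward_bias: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.chromosome_lengths is None:
            self.chromosome_lengths = _default_lengths(self.n_chromosomes)
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ParameterError("chromosome_lengths must have n_chromosomes entries")
        if self.centromere_positions is None:
            self.centromere_positions = [int(0.4 * L) for L in self.chromosome_lengths]
        if len(self.centromere_positions) != self.n_chromosomes:
            raise ParameterError("centromere_positions must have n_chromosomes entries")
        for L, c in zip(self.chromosome_lengths, self.centromere_positions):
            if L <= 0:
                raise ParameterError("chromosome lengths must be positive")
            if not (0 < c < L):
                raise ParameterError(f"centromere position {c} outside chromosome of length {L}")
        for name in ("anchor_spacing_mean", "gene_spacing", "gene_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.nucleus_radius <= 0 or self.step_length <= 0:
            raise ParameterError("nucleus_radius and step_length must be positive")
        if self.step_length > 2 * self.nucleus_radius:
            raise ParameterError(
                f"step_length {self.step_length} exceeds the nucleus diameter "
                f"{2 * self.nucleus_radius}: infeasible geometry"
            )
        if self.seed is None:
            raise ParameterError("seed is mandatory")


def _reflect_into_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point at the sphere surface back inside."""
    r = float(np.linalg.norm(p))
    if r <= radius or r == 0.0:
        return p
    return p * (2 * radius - r) / r


def _walk(rng: np.random.Generator, start: np.ndarray, n_steps: int,
          pole: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Fixed-step random walk biased away from the pole, reflected at the
    nuclear envelope.  Returns (n_steps, 3) positions (start excluded)."""
    out = np.empty((n_steps, 3))
    p = start.copy()
    for s in range(n_steps):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        away = p - pole
        norm = np.linalg.norm(away)
        if norm > 0:
            u = u + params.outward_bias * away / norm
            u /= np.linalg.norm(u)
        p = _reflect_into_sphere(p + params.step_length * u, params.nucleus_radius)
        out[s] = p
    return out


def _anchor_positions(rng: np.random.Generator, length: int, cen: int,
                      mean_spacing: float) -> tuple[np.ndarray, int]:
    """Anchor bp positions for one chromosome: the centromere plus positions
    walking out to both ends with gamma-distributed spacings (positive
    variance, hence non-equidistant anchors).  Returns the sorted positions
    and the index of the centromere anchor."""
    def spacings(total: float) -> list[int]:
        acc, out = 0.0, []
        while acc < total:
            step = max(1.0, rng.gamma(shape=4.0, scale=mean_spacing / 4.0))
            acc += step
            out.append(min(acc, total))
        return out

    left = [cen - s for s in spacings(cen - 1)]
    right = [cen + s for s in spacings(length - cen)]
    pos = np.array(sorted(set(int(p) for p in left)) + [cen]
                   + sorted(set(int(p) for p in right)), dtype=np.int64)
    pos = np.unique(pos)
    cen_idx = int(np.searchsorted(pos, cen))
    return pos, cen_idx


def simulate_genome3d(params: SimulationParams) -> tuple[Model3D, FeatureTable]:
    """Generate a synthetic 3D genome model and a matching gene table.

    Fully reproducible under ``params.seed``.  Every anchor satisfies
    ||P|| <= nucleus_radius; gene ids follow ``G_<CHROM>_<INDEX>``.
    """
    rng = np.random.default_rng(params.seed)
    pole = np.array([0.0, 0.0, -0.9 * params.nucleus_radius])

    model_rows = []
    feature_rows = []
    for c, (length, cen) in enumerate(zip(params.chromosome_lengths,
                                          params.centromere_positions), start=1):
        chrom = f"chr{c:02d}"
        pos, cen_idx = _anchor_positions(rng, length, cen,
                                         params.anchor_spacing_mean)
        cen_anchor = _reflect_into_sphere(
            pole + params.centromere_cluster_sd * rng.normal(size=3),
            params.nucleus_radius,
        )
        n_left = cen_idx
        n_right = len(pos) - cen_idx - 1
        left_path = _walk(rng, cen_anchor, n_left, pole, params)[::-1]
        right_path = _walk(rng, cen_anchor, n_right, pole, params)
        coords = np.vstack([left_path, cen_anchor[None, :], right_path])
        for p, (x, y, z) in zip(pos, coords):
            model_rows.append((chrom, int(p), x, y, z))

        i = 0
        start = 1
        while start + params.gene_length - 1 <= length:
            i += 1
            feature_rows.append((
                f"G_{chrom.upper()}_{i:05d}", chrom, start,
                start + params.gene_length - 1, "gene", "+" if i % 2 else "-",
            ))
            start += params.gene_spacing

    model = Model3D(
        anchors=pd.DataFrame(model_rows,
                             columns=["chromosome", "position", "x", "y", "z"])
        .sort_values(["chromosome", "position"], kind="mergesort")
        .reset_index(drop=True),
        report={"simulated": True, "seed": params.seed},
    )
    model.validate()
    features = FeatureTable(records=pd.DataFrame(
        feature_rows,
        columns=["feature_id", "chromosome", "start", "end", "feature_class",
                 "strand"]))
    return model, features


def sample_random_module(features: FeatureTable, k: int, seed: int,
                         label: str = "random") -> GeneList:
    """Uniform sample of k feature ids without replacement."""
    ids = features.ids
    if k < 1 or k > len(ids):
        raise ParameterError(f"k={k} out of range for {len(ids)} features")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=k, replace=False)
    return GeneList(ids=[ids[i] for i in picked], label=label)


def plant_colocalized_module(coords: CoordinateTable, k: int, radius: float,
                             seed: int, max_attempts: int = 100,
                             label: str = "planted") -> GeneList:
    """Plant a spatially clustered module: k features sampled uniformly from
    within ``radius`` of a random focal feature.

    Retries new focal features up to ``max_attempts`` times; if no ball of
    the given radius contains k features, raises
    :class:`InfeasibleModuleError` reporting the largest achievable size.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    xyz = coords.coords()
    ids = coords.ids
    n = len(ids)
    best = 0
    for _ in range(max_attempts):
        focal = int(rng.integers(n))
        d = np.sqrt(((xyz - xyz[focal]) ** 2).sum(axis=1))
        inside = np.flatnonzero(d <= radius)
        best = max(best, len(inside))
        if len(inside) >= k:
            picked = rng.choice(inside, size=k, replace=False)
            return GeneList(ids=[ids[i] for i in picked], label=label)
    raise InfeasibleModuleError(k, best, radius)
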