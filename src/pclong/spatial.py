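"""Spatial statistics for labeled plasma-cell point patterns.

Implements the nearest-neighbor clustering statistic used to compare
long-lived plasma cells (LLPCs) against the bulk plasma-cell pool: for each
query cell, the mean Euclidean distance to its k nearest cells in a reference
population (default: the *total* pool, both subsets combined, k=20), computed
on a confidence-based random subsample of query cells. Also provides a
grid-density cluster mask for scoring which cells sit inside high-density
plasma-cell clusters, and occupancy/residence statistics of tracked cells
relative to that mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

__all__ = [
    "PointPattern",
    "NNResult",
    "ClusterMask",
    "knn_mean_distance",
    "required_sample_size",
    "subsampled_nn",
    "detect_clusters",
    "cluster_occupancy",
]


@dataclass
class PointPattern:
    """Static positions of cells with subset labels in a bounded region.

    Parameters
    ----------
    positions
        ``(n, d)`` array of coordinates in micrometres, ``d`` in {2, 3}.
    labels
        Length-``n`` array of subset labels (e.g. ``"bulk"``, ``"llpc"``).
    extent
        Box side lengths per axis in micrometres; the region is
        ``[0, extent[j]]`` on each axis.
    """

    positions: np.ndarray
    labels: np.ndarray
    extent: tuple[float, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be an (n, 2) or (n, 3) array")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.positions.shape[0]:
            raise ValueError("labels and positions length mismatch")
        self.extent = tuple(float(e) for e in self.extent)
        if len(self.extent) != self.positions.shape[1]:
            raise ValueError("extent dimensionality mismatch")
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent must be positive on every axis")
        if self.positions.size:
            lo = self.positions.min(axis=0)
            hi = self.positions.max(axis=0)
            if (lo < -1e-9).any() or (hi > np.asarray(self.extent) + 1e-9).any():
                raise ValueError("positions fall outside the declared extent")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def subset(self, label: str) -> np.ndarray:
        """Indices of points carrying ``label``."""
        return np.flatnonzero(self.labels == label)

    def to_frame(self) -> pd.DataFrame:
        cols = ["x_um", "y_um", "z_um"][: self.ndim]
        df = pd.DataFrame(self.positions, columns=cols)
        df["subset"] = self.labels
        return df


@dataclass
class NNResult:
    """Per-cell mean k-nearest-neighbor distances from subsampled iterations."""

    k: int
    n_iterations: int
    sample_size: int
    population: int
    iteration_indices: list[np.ndarray]
    iteration_values: list[np.ndarray]

    @property
    def pooled(self) -> np.ndarray:
        """All per-cell values concatenated across iterations."""
        return np.concatenate(self.iteration_values) if self.iteration_values else np.empty(0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, (idx, vals) in enumerate(
            zip(self.iteration_indices, self.iteration_values), start=1
        ):
            rows.append(
                pd.DataFrame(
                    {"cell_id": idx, "iteration": it, "mean_nn_um": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)


def knn_mean_distance(
    query: np.ndarray,
    reference: np.ndarray,
    k: int = 20,
    query_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Mean Euclidean distance from each query cell to its k nearest reference cells.

    Self-matches are excluded: when ``query_indices`` gives the position of each
    query point inside ``reference``, that entry is never counted among the
    neighbors. The default ``k=20`` follows the field convention of measuring
    distance to the 20 nearest cells of the total plasma-cell pool.

    Raises
    ------
    ValueError
        If fewer than ``k`` eligible reference points exist (no silent
        truncation).
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    n_ref = reference.shape[0]
    self_excluded = query_indices is not None
    eligible = n_ref - 1 if self_excluded else n_ref
    if eligible < k:
        raise ValueError(
            f"reference has only {eligible} eligible points, need k={k}"
        )
    tree = cKDTree(reference)
    if self_excluded:
        dist, idx = tree.query(query, k=k + 1)
        query_indices = np.asarray(query_indices)
        out = np.empty(query.shape[0])
        for i in range(query.shape[0]):
            mask = idx[i] != query_indices[i]
            # self may legitimately be absent from the first k+1 when there
            # are coincident points; keep the k nearest non-self entries
            d = dist[i][mask][:k]
            out[i] = d.mean()
        return out
    dist, _ = tree.query(query, k=k)
    if k == 1:
        dist = dist[:, None]
    return dist.mean(axis=1)


def required_sample_size(
    population: int, confidence: float = 0.95, margin: float = 0.05
) -> int:
    """Cochran sample size with finite-population correction, rounded up.

    ``n0 = z^2 * 0.25 / margin^2`` with ``z`` the two-sided normal quantile for
    ``confidence`` (maximal-variance proportion p = 0.5), then
    ``n = n0 / (1 + (n0 - 1) / population)``, ceiling, capped at the
    population. At 95% confidence / 5% margin: N=1000 -> 278, N=100 -> 80.
    """
    if population < 1:
        raise ValueError("population must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if not 0 < margin < 1:
        raise ValueError("margin must lie in (0, 1)")
    z = norm.ppf(1 - (1 - confidence) / 2)
    n0 = z * z * 0.25 / (margin * margin)
    n = n0 / (1 + (n0 - 1) / population)
    return min(int(math.ceil(n - 1e-12)), population)


def subsampled_nn(
    pattern: PointPattern,
    query_label: str,
    k: int = 20,
    n_iterations: int = 2,
    confidence: float = 0.95,
    margin: float = 0.05,
    seed: int | None = None,
) -> NNResult:
    """k-NN mean distance on confidence-sized random subsamples of one subset.

    Query cells carry ``query_label``; the reference set is the *whole*
    pattern (both subsets), with each query cell excluded from its own
    neighbor list. The subsample size comes from :func:`required_sample_size`
    on the subset population; drawing is uniform without replacement and is
    repeated ``n_iterations`` times with independent draws (default 2).
    """
    query_idx = pattern.subset(query_label)
    population = query_idx.size
    if population == 0:
        raise ValueError(f"no cells labeled {query_label!r}")
    size = required_sample_size(population, confidence, margin)
    rng = np.random.default_rng(seed)
    it_indices: list[np.ndarray] = []
    it_values: list[np.ndarray] = []
    for _ in range(n_iterations):
        chosen = np.sort(rng.choice(query_idx, size=size, replace=False))
        vals = knn_mean_distance(
            pattern.positions[chosen], pattern.positions, k=k, query_indices=chosen
        )
        it_indices.append(chosen)
        it_values.append(vals)
    return NNResult(
        k=k,
        n_iterations=n_iterations,
        sample_size=size,
        population=population,
        iteration_indices=it_indices,
        iteration_values=it_values,
    )


@dataclass
class ClusterMask:
    """High-density region mask on a regular grid.

    ``bin_clusters`` maps occupied bin indices (tuples) to a 1-based cluster
    ID; ``cluster_counts`` gives the total cell count per cluster.
    """

    origin: tuple[float, ...]
    bin_size: float
    grid_shape: tuple[int, ...]
    bin_clusters: dict[tuple[int, ...], int] = field(default_factory=dict)
    cluster_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_counts)

    def bin_index(self, positions: np.ndarray) -> np.ndarray:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        return np.floor(
            (positions - np.asarray(self.origin)) / self.bin_size
        ).astype(int)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean: does each position fall in a masked (cluster) bin."""
        idx = self.bin_index(positions)
        return np.array(
            [tuple(row) in self.bin_clusters for row in idx], dtype=bool
        )

    def cluster_of(self, positions: np.ndarray) -> np.ndarray:
        """Cluster ID per position (0 = outside every cluster)."""
        idx = self.bin_index(positions)
        return np.array(
            [self.bin_clusters.get(tuple(row), 0) for row in idx], dtype=int
        )


def detect_clusters(
    pattern: PointPattern,
    bin_size: float,
    min_count_per_bin: int,
    min_cells_per_cluster: int = 1,
) -> ClusterMask:
    """Grid-density cluster detection with full-connectivity components.

    Bins of side ``bin_size`` holding at least ``min_count_per_bin`` cells are
    masked; masked bins touching by face, edge or corner merge into one
    cluster; clusters holding fewer than ``min_cells_per_cluster`` cells in
    total are discarded. An empty pattern yields an empty mask.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    d = len(pattern.extent)
    shape = tuple(int(math.ceil(e / bin_size)) for e in pattern.extent)
    origin = (0.0,) * d
    mask = ClusterMask(origin=origin, bin_size=float(bin_size), grid_shape=shape)
    if pattern.n == 0:
        return mask
    bin_idx = np.floor(pattern.positions / bin_size).astype(int)
    # points exactly on the upper boundary belong to the last bin
    bin_idx = np.minimum(bin_idx, np.asarray(shape) - 1)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(bin_idx.T), 1)
    dense = counts >= min_count_per_bin
    structure = np.ones((3,) * d, dtype=int)  # face+edge+corner adjacency
    labeled, n_comp = ndimage.label(dense, structure=structure)
    next_id = 1
    for comp in range(1, n_comp + 1):
        comp_bins = np.argwhere(labeled == comp)
        total = int(counts[tuple(comp_bins.T)].sum())
        if total < min_cells_per_cluster:
            continue
        for b in comp_bins:
            mask.bin_clusters[tuple(int(v) for v in b)] = next_id
        mask.cluster_counts[next_id] = total
        next_id += 1
    return mask


def cluster_occupancy(tracks, mask: ClusterMask):
    """Occupancy of cluster regions by tracked cells, per subset and per cell.

    For every frame time, computes the fraction of each subset's cells whose
    position falls inside a masked bin; per cell, the residence time is the
    number of inside frames times the frame interval.

    Parameters
    ----------
    tracks
        Iterable of :class:`pclong.tracks.Track`; each must carry a
        ``subset`` entry in its metadata and share the mask's coordinate
        frame.
    mask
        Cluster mask from :func:`detect_clusters`.

    Returns
    -------
    (occupancy, residence)
        ``occupancy``: DataFrame with columns ``t_min, subset,
        inside_fraction, n_cells``; ``inside + outside`` fractions sum to 1.
        ``residence``: DataFrame with columns ``track_id, subset,
        residence_min, duration_min, inside_fraction``.
    """
    occ_rows = []
    res_rows = []
    frame_map: dict[tuple[float, str], list[bool]] = {}
    for tr in tracks:
        if tr.positions.shape[1] != len(mask.origin):
            raise ValueError("track/mask dimension mismatch")
        subset = tr.metadata.get("subset", tr.metadata.get("phenotype", "all"))
        inside = mask.contains(tr.positions)
        dt = np.diff(tr.t)
        interval = float(np.median(dt)) if dt.size else 0.0
        res_rows.append(
            {
                "track_id": tr.track_id,
                "subset": subset,
                "residence_min": float(inside.sum() * interval),
                "duration_min": float(tr.t[-1] - tr.t[0]) if tr.t.size > 1 else 0.0,
                "inside_fraction": float(inside.mean()) if inside.size else 0.0,
            }
        )
        for t, flag in zip(tr.t, inside):
            frame_map.setdefault((float(t), subset), []).append(bool(flag))
    for (t, subset), flags in sorted(frame_map.items()):
        occ_rows.append(
            {
                "t_min": t,
                "subset": subset,
                "inside_fraction": float(np.mean(flags)),
                "n_cells": len(flags),
            }
        )
    return pd.DataFrame(occ_rows), pd.DataFrame(res_rows)
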