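"""Graphs giving superpixels local context, and mesh strain vectors.

Two neighbourhood notions are used downstream:

* the *static mesh*: superpixels are neighbours if their **frame-0**
  centroids lie within a radius; the adjacency is then frozen for the whole
  video, so mesh distortion measures departure from the initial geometry
  (the working assumption of collective sheet migration is that initially
  close superpixels stay close);
* the *radius-neighbour graph*: neighbours are recomputed per frame from
  current positions, so node degree tracks where motion concentrates.

Radii are expressed in pixels; callers usually derive them as a multiple of
the grid's average superpixel width (1.2x for strain meshes, 5x for motion
saliency).  Distance comparisons are inclusive (``<= radius``) so that the
exact-distance case is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .exceptions import InvalidArgumentError
from .tracking import TrackArray

__all__ = [
    "MeshStatic",
    "build_static_mesh",
    "build_radius_graph",
    "build_knn_graph",
    "mesh_strain_vector",
    "adjacency_from_pairs",
]


@dataclass
class MeshStatic:
    """Frozen frame-0 radius mesh: symmetric boolean adjacency, no self-edges."""

    adjacency: sp.csr_matrix
    radius: float
    radius_factor: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of i < j edges."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


def adjacency_from_pairs(n: int, pairs: np.ndarray) -> sp.csr_matrix:
    """Symmetric boolean CSR adjacency from an iterable of (i, j) pairs."""
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    if len(pairs):
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(len(i), dtype=np.int8)
        adj = sp.coo_matrix((data, (i, j)), shape=(n, n)).tocsr()
        adj.data[:] = 1  # collapse duplicates
    else:
        adj = sp.csr_matrix((n, n), dtype=np.int8)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj


def build_radius_graph(positions: np.ndarray, radius: float) -> sp.csr_matrix:
    """Symmetric adjacency linking points within ``radius`` (inclusive)."""
    positions = np.asarray(positions, dtype=float)
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    tree = cKDTree(positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    return adjacency_from_pairs(len(positions), pairs)


def build_static_mesh(
    tracks: TrackArray | np.ndarray,
    avg_width: float,
    radius_factor: float = 1.2,
) -> MeshStatic:
    """Radius mesh on frame-0 centroids, frozen for the whole video.

    ``radius_factor`` multiplies ``avg_width``; the default 1.2 links each
    interior node of a regular grid to its 4-connected lattice neighbours
    (diagonals sit at sqrt(2) ~ 1.414 widths and are excluded).
    """
    if radius_factor <= 0:
        raise InvalidArgumentError("radius_factor must be positive")
    pos0 = tracks.positions[:, 0] if isinstance(tracks, TrackArray) else np.asarray(tracks)
    radius = radius_factor * avg_width
    return MeshStatic(
        adjacency=build_radius_graph(pos0, radius),
        radius=radius,
        radius_factor=radius_factor,
    )


def build_knn_graph(positions: np.ndarray, k: int) -> sp.csr_matrix:
    """k-nearest-neighbour graph, symmetrized by union.

    Distance ties are broken by lower point index so the graph is
    deterministic for degenerate geometries.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if not (1 <= k < n):
        raise InvalidArgumentError(f"k must be in [1, {n - 1}]; got {k}")
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    pairs = []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d[i]))[:k]
        pairs.extend((i, j) for j in order)
    return adjacency_from_pairs(n, np.asarray(pairs))


def mesh_strain_vector(
    tracks: TrackArray, mesh: MeshStatic, t: int
) -> np.ndarray:
    """Resultant mesh strain vector per superpixel at frame ``t``.

    For node i with mesh neighbours N_i,

        d_i(t) = sum_{j in N_i} [(r_i(t) - r_j(t)) - (r_i(t-1) - r_j(t-1))]

    i.e. the frame-to-frame change of each relative displacement, summed
    over neighbours.  This vanishes identically under rigid translation and
    varies more smoothly than instantaneous velocity.  Isolated nodes get a
    zero vector.
    """
    if t < 1 or t >= tracks.n_frames:
        raise InvalidArgumentError(f"t must be in [1, {tracks.n_frames - 1}]")
    v = tracks.positions[:, t] - tracks.positions[:, t - 1]  # (n, 2)
    deg = mesh.degrees()[:, None]
    return deg * v - mesh.adjacency @ v
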