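"""Superpixel grid construction and long-time track propagation.

The motion representation is deliberately cell-free: the first frame is
partitioned into a regular grid of near-square "superpixels", a dense
optical-flow field is estimated between every consecutive frame pair, and
each superpixel centroid is advected by the mean flow over the image area
the superpixel currently covers.  Concatenating the per-frame positions
yields long-time tracks without ever detecting or linking individual cells.

Conventions
-----------
* ``x`` is the column coordinate, ``y`` the row coordinate, both 0-based
  with the origin at the top-left corner of the frame.
* A flow field is stored as an ``(H, W, 2)`` array whose last axis holds
  ``(dx, dy)`` in pixels per frame pair.
* Track positions are stored as ``(n_superpixels, n_frames, 2)`` arrays of
  ``(x, y)``.  Displacement increments are rounded to the nearest integer
  by default, so a position is always the frame-0 centroid plus an integer
  cumulative displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

from .exceptions import InvalidArgumentError

__all__ = [
    "VideoStack",
    "SuperpixelGrid",
    "TrackArray",
    "make_superpixel_grid",
    "estimate_flow",
    "estimate_flow_sequence",
    "propagate_tracks",
    "spawn_dense_superpixels",
    "register_flow_backend",
    "FLOW_BACKENDS",
]


@dataclass
class VideoStack:
    """A timelapse video: ``frames`` indexed ``(time, row, col, channel)``.

    ``frame_interval`` is metadata only (hours per frame; acquisition in the
    assays this package targets is typically one frame per hour).
    """

    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 3:  # single channel
            frames = frames[..., None]
        if frames.ndim != 4:
            raise InvalidArgumentError(
                f"frames must be (T, H, W[, C]); got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise InvalidArgumentError("a video needs at least 2 frames")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[3]

    def channel(self, index: int) -> np.ndarray:
        """Single-channel view, shape (T, H, W)."""
        return self.frames[..., index]


@dataclass
class SuperpixelGrid:
    """Regular near-square partition of the frame-0 image plane.

    ``labels`` assigns every pixel to exactly one region 0..n-1;
    ``centroids`` are the (x, y) region centres; ``avg_width`` is
    ``sqrt(H*W / n_target)``, the nominal superpixel edge length used as
    the length unit for all mesh radii.
    """

    labels: np.ndarray
    centroids: np.ndarray
    avg_width: float

    @property
    def n_superpixels(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_pixels(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) arrays of the pixels in region ``i``."""
        return np.nonzero(self.labels == i)

    def region_areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_superpixels)


@dataclass
class TrackArray:
    """Long-time superpixel tracks.

    ``positions`` is ``(n, T, 2)`` of (x, y); ``spawn_frame[i]`` is the frame
    at which track i was seeded (0 for the fixed frame-0 grid); ``origin``
    flags each track ``"fixed"`` or ``"dense-spawned"``.  A track whose
    footprint has fully left the frame holds its last position.
    """

    positions: np.ndarray
    spawn_frame: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise InvalidArgumentError(
                f"positions must be (n, T, 2); got {self.positions.shape}"
            )
        n = self.positions.shape[0]
        if self.spawn_frame is None:
            self.spawn_frame = np.zeros(n, dtype=int)
        else:
            self.spawn_frame = np.asarray(self.spawn_frame, dtype=int)
        if self.origin is None:
            self.origin = np.array(["fixed"] * n, dtype=object)
        else:
            self.origin = np.asarray(self.origin, dtype=object)

    @property
    def n_tracks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def velocities(self) -> np.ndarray:
        """Per-frame displacement V(t) = r(t+1) - r(t), shape (n, T-1, 2)."""
        return np.diff(self.positions, axis=1)

    def path_length(self, n_steps: int | None = None) -> np.ndarray:
        """Cumulative moved distance over the first ``n_steps`` frame pairs."""
        v = self.velocities()
        if n_steps is not None:
            v = v[:, :n_steps]
        return np.linalg.norm(v, axis=2).sum(axis=1)


# ---------------------------------------------------------------------------
# superpixel grid


def make_superpixel_grid(height: int, width: int, n_target: int) -> SuperpixelGrid:
    """Partition an ``height x width`` frame into ~``n_target`` square tiles.

    The actual count is ``n_rows * n_cols`` with the tile aspect chosen as
    close to square as the frame allows; for 1000 superpixels on a
    1344 x 1024 frame the nominal width is sqrt(H*W/1000) ~ 37 px.
    """
    if height < 1 or width < 1:
        raise InvalidArgumentError("frame dimensions must be >= 1")
    if not (1 <= n_target <= height * width):
        raise InvalidArgumentError(
            f"n_target must be in [1, {height * width}]; got {n_target}"
        )
    avg_width = float(np.sqrt(height * width / n_target))
    # candidate row/col counts bracketing H/avg and W/avg; pick the product
    # closest to n_target (ties: more regions)
    r0 = height / avg_width
    c0 = width / avg_width
    cands = []
    for nr in {max(1, int(np.floor(r0))), max(1, int(np.ceil(r0))), max(1, round(r0))}:
        for nc in {max(1, int(np.floor(c0))), max(1, int(np.ceil(c0))), max(1, round(c0))}:
            if nr <= height and nc <= width:
                cands.append((abs(nr * nc - n_target), -nr * nc, nr, nc))
    _, _, n_rows, n_cols = min(cands)

    row_edges = np.linspace(0, height, n_rows + 1).round().astype(int)
    col_edges = np.linspace(0, width, n_cols + 1).round().astype(int)
    row_idx = np.searchsorted(row_edges, np.arange(height), side="right") - 1
    col_idx = np.searchsorted(col_edges, np.arange(width), side="right") - 1
    labels = (row_idx[:, None] * n_cols + col_idx[None, :]).astype(np.int32)

    # exact pixel-mean centroids of each rectangular tile
    row_c = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    col_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    cx, cy = np.meshgrid(col_c, row_c)
    centroids = np.column_stack([cx.ravel(), cy.ravel()])
    return SuperpixelGrid(labels=labels, centroids=centroids, avg_width=avg_width)


# ---------------------------------------------------------------------------
# dense optical flow


def _ilk_backend(a: np.ndarray, b: np.ndarray, **params) -> np.ndarray:
    v, u = optical_flow_ilk(a, b, **params)
    return np.stack([u, v], axis=-1)


def _tvl1_backend(a: np.ndarray, b: np.ndarray, **params) -> np.ndarray:
    v, u = optical_flow_tvl1(a, b, **params)
    return np.stack([u, v], axis=-1)


#: Registered dense-flow estimators.  Each maps two single-channel float
#: images to an (H, W, 2) displacement field holding (dx, dy) per pixel.
FLOW_BACKENDS: dict[str, Callable[..., np.ndarray]] = {
    "ilk": _ilk_backend,
    "tvl1": _tvl1_backend,
}

DEFAULT_FLOW_BACKEND = "ilk"


def register_flow_backend(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register a custom dense-flow estimator under ``name``.

    The backend is intentionally pluggable so that flow models tailored to
    other imaging physics can be swapped in without touching the tracker.
    """
    FLOW_BACKENDS[name] = fn


def estimate_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    backend: str = DEFAULT_FLOW_BACKEND,
    **params,
) -> np.ndarray:
    """Dense per-pixel displacement from ``frame_a`` to ``frame_b``.

    Returns an ``(H, W, 2)`` array of ``(dx, dy)``.  Deterministic for fixed
    inputs and parameters.
    """
    a = np.asarray(frame_a, dtype=np.float32)
    b = np.asarray(frame_b, dtype=np.float32)
    if a.ndim != 2 or b.ndim != 2:
        raise InvalidArgumentError("frames must be single-channel 2-D images")
    if a.shape != b.shape:
        raise InvalidArgumentError(f"frame shapes differ: {a.shape} vs {b.shape}")
    try:
        fn = FLOW_BACKENDS[backend]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown flow backend {backend!r}; registered: {sorted(FLOW_BACKENDS)}"
        ) from None
    flow = np.asarray(fn(a, b, **params), dtype=np.float64)
    if flow.shape != a.shape + (2,):
        raise InvalidArgumentError(
            f"backend returned shape {flow.shape}, expected {a.shape + (2,)}"
        )
    return np.nan_to_num(flow, copy=False)


def estimate_flow_sequence(
    frames: np.ndarray,
    backend: str = DEFAULT_FLOW_BACKEND,
    **params,
) -> np.ndarray:
    """Flow fields for every consecutive pair of a (T, H, W) stack."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise InvalidArgumentError("expected a (T, H, W) single-channel stack")
    return np.stack(
        [
            estimate_flow(frames[t], frames[t + 1], backend=backend, **params)
            for t in range(frames.shape[0] - 1)
        ]
    )


# ---------------------------------------------------------------------------
# track propagation


def _region_pixel_lists(labels: np.ndarray, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    order = np.argsort(labels.ravel(), kind="stable")
    counts = np.bincount(labels.ravel(), minlength=n)
    rows, cols = np.unravel_index(order, labels.shape)
    out = []
    start = 0
    for c in counts:
        out.append((rows[start : start + c], cols[start : start + c]))
        start += c
    return out


def propagate_tracks(
    flows: Sequence[np.ndarray] | np.ndarray,
    grid: SuperpixelGrid,
    mode: str = "fixed",
    round_displacement: bool = True,
) -> TrackArray:
    """Advect superpixel centroids through a sequence of flow fields.

    Each step averages the flow over the superpixel's current footprint —
    the frame-0 label mask translated by the integer cumulative displacement
    and clipped to the frame (area lost off-frame is not recovered).  The
    mean displacement is rounded to the nearest integer before being applied.
    A superpixel whose footprint has no in-frame pixels left freezes and
    retains its last position.

    ``mode="dense"`` additionally seeds new superpixels each frame at the
    centres of grid cells vacated by all current centroids, so coverage of
    newly exposed image area is maintained.
    """
    if mode not in ("fixed", "dense"):
        raise InvalidArgumentError(f"mode must be 'fixed' or 'dense', got {mode!r}")
    flows = [np.asarray(f, dtype=float) for f in flows]
    if len(flows) == 0:
        raise InvalidArgumentError("flow sequence is empty")
    H, W = grid.shape
    for f in flows:
        if f.shape != (H, W, 2):
            raise InvalidArgumentError(
                f"flow shape {f.shape} does not match grid {(H, W)}"
            )
    T = len(flows) + 1

    n0 = grid.n_superpixels
    footprints = _region_pixel_lists(grid.labels, n0)
    positions = [grid.centroids.copy()]  # list of (n_t, 2) per frame
    cum = np.zeros((n0, 2))  # cumulative (dx, dy); integer-valued if rounding
    frozen = np.zeros(n0, dtype=bool)
    spawn_frame = [0] * n0
    origin = ["fixed"] * n0
    spawn_pos: list[np.ndarray] = []

    for t in range(T - 1):
        flow = flows[t]
        n_cur = len(footprints)
        step = np.zeros((n_cur, 2))
        for i in range(n_cur):
            if frozen[i]:
                continue
            dx, dy = cum[i]
            rr = footprints[i][0] + int(round(dy))
            cc = footprints[i][1] + int(round(dx))
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            if not ok.any():
                frozen[i] = True
                continue
            mdx = flow[rr[ok], cc[ok], 0].mean()
            mdy = flow[rr[ok], cc[ok], 1].mean()
            if round_displacement:
                mdx, mdy = np.rint(mdx), np.rint(mdy)
            step[i] = (mdx, mdy)
        cum[:n_cur] += step
        new_pos = positions[-1] + step
        positions.append(new_pos)

        if mode == "dense":
            # cells of the original tiling containing no current centroid
            vacated = _vacated_cells(grid, new_pos)
            if len(vacated):
                for cell in vacated:
                    footprints.append(footprints[cell])
                    spawn_frame.append(t + 1)
                    origin.append("dense-spawned")
                    spawn_pos.append(grid.centroids[cell])
                k = len(vacated)
                cum = np.vstack([cum, np.zeros((k, 2))])
                frozen = np.concatenate([frozen, np.zeros(k, dtype=bool)])
                add = np.asarray([grid.centroids[c] for c in vacated], dtype=float)
                positions[-1] = np.vstack([positions[-1], add])

    n_final = len(footprints)
    out = np.empty((n_final, T, 2))
    for t, pos in enumerate(positions):
        out[: len(pos), t] = pos
    # tracks spawned later: fill earlier frames with the spawn position
    for i in range(n0, n_final):
        s = spawn_frame[i]
        out[i, :s] = spawn_pos[i - n0]
    return TrackArray(
        positions=out,
        spawn_frame=np.asarray(spawn_frame),
        origin=np.asarray(origin, dtype=object),
    )


def _vacated_cells(grid: SuperpixelGrid, current_positions: np.ndarray) -> np.ndarray:
    """Original grid cells whose area contains no current centroid."""
    H, W = grid.shape
    x = np.clip(np.rint(current_positions[:, 0]).astype(int), 0, W - 1)
    y = np.clip(np.rint(current_positions[:, 1]).astype(int), 0, H - 1)
    occupied = np.zeros(grid.n_superpixels, dtype=bool)
    occupied[grid.labels[y, x]] = True
    return np.flatnonzero(~occupied)


def spawn_dense_superpixels(
    tracks: TrackArray, grid: SuperpixelGrid, frame: int
) -> TrackArray:
    """Seed new constant-history tracks in grid cells vacated at ``frame``.

    New tracks start at the vacated cell centres; their positions before
    ``frame`` are filled with the spawn position.  Existing tracks are
    unchanged, so the superpixel count is non-decreasing.
    """
    if not (0 <= frame < tracks.n_frames):
        raise InvalidArgumentError(f"frame {frame} out of range")
    vacated = _vacated_cells(grid, tracks.positions[:, frame])
    if len(vacated) == 0:
        return tracks
    T = tracks.n_frames
    add = np.repeat(grid.centroids[vacated][:, None, :], T, axis=1)
    positions = np.concatenate([tracks.positions, add], axis=0)
    spawn = np.concatenate([tracks.spawn_frame, np.full(len(vacated), frame)])
    origin = np.concatenate(
        [tracks.origin, np.array(["dense-spawned"] * len(vacated), dtype=object)]
    )
    return TrackArray(positions=positions, spawn_frame=spawn, origin=origin)
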