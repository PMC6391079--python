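"""Motion-based assignment of superpixels to migrating sheets.

Two dyed cell populations are tracked independently on the same superpixel
grid, once per colour channel.  Background regions, autofluorescent debris
and isolated cells produce tracks that are biologically irrelevant; this
module keeps only the superpixels belonging to each moving sheet, using
motion information alone:

1. threshold on the distance moved within an early window (default the
   first 2 frame pairs);
2. keep the largest spatially connected component of those movers
   (radius graph on frame-0 centroids, 1.2 average widths);
3. if a channel claims an implausibly large frame fraction (above a
   user-set coverage cut-off, default 0.70 for 50:50 platings), award
   superpixels claimed by both channels to the channel in which they moved
   farther over the early window;
4. (fixed-grid tracking only) activate extra superpixels frame-by-frame
   when their tracked centroid enters the area currently covered by kept
   superpixels;
5. re-run steps 1-2 on the enlarged set;
6. reset every non-kept track to a constant at its frame-0 centroid so the
   track count per channel is unchanged — cohorts stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .exceptions import InvalidArgumentError
from .meshes import adjacency_from_pairs
from .tracking import SuperpixelGrid, TrackArray

__all__ = [
    "SheetAssignment",
    "AssignmentParams",
    "threshold_moving_superpixels",
    "largest_motion_component",
    "assign_sheet_superpixels",
]


@dataclass
class AssignmentParams:
    """Tunable knobs of the assignment procedure (all in grid units)."""

    n_early_frames: int = 2
    dist_thresh_factor: float = 0.1  # x avg_width, over the early window
    radius_factor: float = 1.2  # x avg_width, for the component graph
    coverage_cutoff: float = 0.70
    run_step5: bool = True
    dynamic_activation: bool = True  # step 4; disable for dense tracking


@dataclass
class SheetAssignment:
    """Per-channel kept / frozen index sets plus claimed area fractions."""

    kept: dict[str, np.ndarray]
    frozen: dict[str, np.ndarray]
    coverage_fraction: dict[str, float]


def threshold_moving_superpixels(
    tracks: TrackArray, n_early_frames: int = 2, dist_thresh: float = 0.0
) -> np.ndarray:
    """Indices whose cumulative path length over the first ``n_early_frames``
    frame pairs exceeds ``dist_thresh``."""
    if not (1 <= n_early_frames < tracks.n_frames):
        raise InvalidArgumentError(
            f"n_early_frames must be in [1, {tracks.n_frames - 1}]"
        )
    moved = tracks.path_length(n_early_frames)
    return np.flatnonzero(moved > dist_thresh)


def largest_motion_component(
    indices: np.ndarray, centroids: np.ndarray, radius: float
) -> np.ndarray:
    """Largest connected component of the radius graph on the given subset.

    Ties between equally large components are broken in favour of the one
    containing the smallest index.
    """
    indices = np.asarray(indices, dtype=int)
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    if len(indices) == 0:
        return indices
    pts = np.asarray(centroids, dtype=float)[indices]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    adj = adjacency_from_pairs(len(indices), pairs)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(range(n_comp), key=lambda c: (sizes[c], -indices[labels == c].min()))
    return indices[labels == best]


def _steps_1_2(
    tracks: TrackArray,
    grid: SuperpixelGrid,
    params: AssignmentParams,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    thresh = params.dist_thresh_factor * grid.avg_width
    moving = threshold_moving_superpixels(tracks, params.n_early_frames, thresh)
    if subset is not None:
        moving = np.intersect1d(moving, subset)
    return largest_motion_component(
        moving, grid.centroids, params.radius_factor * grid.avg_width
    )


def _coverage(kept: np.ndarray, grid: SuperpixelGrid) -> float:
    areas = grid.region_areas()
    H, W = grid.shape
    return float(areas[kept].sum() / (H * W))


def _covered_mask_at(
    tracks: TrackArray,
    grid: SuperpixelGrid,
    kept: np.ndarray,
    t: int,
    region_pixels: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Union of kept superpixels' frame-0 regions translated to frame ``t``."""
    H, W = grid.shape
    mask = np.zeros((H, W), dtype=bool)
    kept = np.asarray(kept, dtype=int)
    if len(kept) == 0:
        return mask
    disp = np.rint(tracks.positions[kept, t] - tracks.positions[kept, 0]).astype(int)
    for k, i in enumerate(kept):
        rr = region_pixels[i][0] + disp[k, 1]
        cc = region_pixels[i][1] + disp[k, 0]
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        mask[rr[ok], cc[ok]] = True
    return mask


def assign_sheet_superpixels(
    tracks_red: TrackArray,
    tracks_green: TrackArray,
    grid: SuperpixelGrid,
    params: AssignmentParams | None = None,
) -> tuple[SheetAssignment, TrackArray, TrackArray]:
    """Run the full six-step assignment on a two-channel track pair.

    Returns the assignment plus new track arrays in which every non-kept
    track is a constant at its frame-0 centroid (shape preserved).
    """
    params = params or AssignmentParams()
    if not (0 < params.coverage_cutoff <= 1):
        raise InvalidArgumentError("coverage_cutoff must be in (0, 1]")
    channels = {"red": tracks_red, "green": tracks_green}
    kept = {c: _steps_1_2(tr, grid, params) for c, tr in channels.items()}
    coverage = {c: _coverage(kept[c], grid) for c in channels}

    # step 3: joint degree-of-movement filtering when a channel over-claims
    if any(coverage[c] > params.coverage_cutoff for c in channels):
        contested = np.intersect1d(kept["red"], kept["green"])
        if len(contested):
            moved = {
                c: channels[c].path_length(params.n_early_frames)
                for c in channels
            }
            red_wins = moved["red"][contested] >= moved["green"][contested]
            kept["red"] = np.setdiff1d(kept["red"], contested[~red_wins])
            kept["green"] = np.setdiff1d(kept["green"], contested[red_wins])

    # step 4: dynamic activation (fixed-grid tracking)
    if params.dynamic_activation:
        from .tracking import _region_pixel_lists

        region_pixels = _region_pixel_lists(grid.labels, grid.n_superpixels)
        for c, tr in channels.items():
            current = set(kept[c].tolist())
            others = np.setdiff1d(np.arange(tr.n_tracks), kept[c])
            for t in range(1, tr.n_frames):
                if len(others) == 0 or len(current) == 0:
                    break
                mask = _covered_mask_at(
                    tr, grid, np.asarray(sorted(current)), t, region_pixels
                )
                H, W = grid.shape
                x = np.clip(np.rint(tr.positions[others, t, 0]).astype(int), 0, W - 1)
                y = np.clip(np.rint(tr.positions[others, t, 1]).astype(int), 0, H - 1)
                hit = mask[y, x]
                if hit.any():
                    current.update(others[hit].tolist())
                    others = others[~hit]
            kept[c] = np.asarray(sorted(current), dtype=int)

        # step 5: repeat steps 1-2 restricted to the activated set
        if params.run_step5:
            for c, tr in channels.items():
                kept[c] = _steps_1_2(tr, grid, params, subset=kept[c])

    # step 6: constant tracks for everything else
    out_tracks = {}
    frozen = {}
    for c, tr in channels.items():
        frozen[c] = np.setdiff1d(np.arange(tr.n_tracks), kept[c])
        pos = tr.positions.copy()
        pos[frozen[c]] = pos[frozen[c], :1]
        out_tracks[c] = TrackArray(
            positions=pos, spawn_frame=tr.spawn_frame.copy(), origin=tr.origin.copy()
        )
        coverage[c] = _coverage(kept[c], grid)

    assignment = SheetAssignment(kept=kept, frozen=frozen, coverage_fraction=coverage)
    return assignment, out_tracks["red"], out_tracks["green"]
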