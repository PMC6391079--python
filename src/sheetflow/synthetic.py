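"""Ground-truthed synthetic inputs: point-process tracks and rendered
two-sheet gap-closure videos.

The video generator emulates the classic two-population migration assay:
two textured cell sheets, one per colour channel, advance across a central
gap until they meet.  What happens after contact is scripted per scenario:

* ``coalesce`` — the fronts keep advancing briefly and interpenetrate, as
  when two sheets of the same cell type merge;
* ``stable_boundary`` — both sheets stop dead at the contact line, the
  signature of a sharp heterotypic boundary;
* ``push_through`` — the left sheet keeps advancing at full speed and
  displaces the right sheet, which retreats rigidly.

Motion is a piecewise-constant velocity field applied to a granular blob
texture (no mechanics are simulated); the texture gives dense optical flow
something to lock onto.  Ground truth (closure frame, interface trajectory,
per-frame sheet masks) is recorded analytically from the kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .exceptions import InvalidArgumentError
from .measures import SaliencyMap
from .tracking import TrackArray, VideoStack, make_superpixel_grid

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "simulate_brownian_tracks",
    "simulate_ballistic_tracks",
    "render_two_sheet_video",
    "make_saliency_fixture",
]

SCENARIOS = ("coalesce", "stable_boundary", "push_through")


@dataclass
class ScenarioSpec:
    """Parameters of a rendered two-sheet gap-closure video.

    Defaults are a desk-scale version of the assay geometry: a 256 x 320
    frame (the acquired videos are 512 x 672 and upward), a 120 px central
    gap, symmetric front speeds of 3 px/frame and one frame per nominal
    hour for 60 frames, blob texture grain ~8 px and mild additive noise.
    """

    scenario: str = "stable_boundary"
    shape: tuple[int, int] = (256, 320)
    gap_width: float = 120.0
    speed_left: float = 3.0
    speed_right: float = 3.0
    n_frames: int = 60
    grain: float = 8.0
    noise_sigma: float = 2.0
    background_amp: float = 8.0  # static background structure, grey levels
    seed: int = 0
    coalesce_overlap: float = 20.0  # px of interpenetration before stopping

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidArgumentError(
                f"scenario must be one of {SCENARIOS}; got {self.scenario!r}"
            )
        if not (0 < self.gap_width < self.shape[1]):
            raise InvalidArgumentError("gap width must be positive and < frame width")
        if self.speed_left <= 0 or self.speed_right <= 0:
            raise InvalidArgumentError("sheet speeds must be positive")


@dataclass
class GroundTruth:
    """Analytic truth accompanying a rendered video."""

    closure_frame: int
    boundary_x: np.ndarray  # per-frame interface column (midgap before contact)
    left_front: np.ndarray  # per-frame right edge of the left sheet
    right_front: np.ndarray  # per-frame left edge of the right sheet

    def sheet_masks(self, shape: tuple[int, int], t: int) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (red, green) sheet masks at frame ``t``."""
        cols = np.arange(shape[1])
        left = cols <= self.left_front[t]
        right = cols >= self.right_front[t]
        return (
            np.broadcast_to(left, shape).copy(),
            np.broadcast_to(right, shape).copy(),
        )


# ---------------------------------------------------------------------------
# point-process tracks


def simulate_brownian_tracks(
    n: int, T: int, sigma: float, seed: int = 0, box: float = 0.0
) -> TrackArray:
    """2-D Gaussian random walks: i.i.d. N(0, sigma^2) steps per component.

    Start positions are spread uniformly over ``[0, box]^2`` (all at the
    origin when box = 0).  MSD grows linearly, exponent alpha ~ 1.
    """
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, box, size=(n, 1, 2)) if box > 0 else np.zeros((n, 1, 2))
    steps = rng.normal(0.0, sigma, size=(n, T - 1, 2)) if sigma > 0 else np.zeros((n, T - 1, 2))
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    return TrackArray(positions=pos + start)


def simulate_ballistic_tracks(
    n: int, T: int, speed: float = 1.0, seed: int = 0, box: float = 0.0
) -> TrackArray:
    """Straight-line tracks with constant per-track heading and speed.

    RMSD(t) = speed * t exactly; MSD exponent alpha = 2.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    vel = speed * np.column_stack([np.cos(theta), np.sin(theta)])  # (n, 2)
    t = np.arange(T)[None, :, None]
    start = rng.uniform(0, box, size=(n, 1, 2)) if box > 0 else np.zeros((n, 1, 2))
    return TrackArray(positions=start + vel[:, None, :] * t)


# ---------------------------------------------------------------------------
# two-sheet videos


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Static smooth random field in [0, 1] (background structure)."""
    f = gaussian_filter(rng.random(shape), 2.0)
    return (f - f.min()) / (f.max() - f.min() + 1e-12)


def _blob_texture(shape: tuple[int, int], grain: float, rng: np.random.Generator) -> np.ndarray:
    """Granular blob texture in [0, 1] with feature size ~``grain`` px."""
    noise = rng.random(shape)
    smooth = gaussian_filter(noise, sigma=grain / 2.0, mode="wrap")
    thr = np.percentile(smooth, 55)
    blobs = (smooth > thr).astype(float)
    # soften edges slightly so sub-pixel advection stays trackable
    return gaussian_filter(blobs, sigma=1.0, mode="wrap")


def _sheet_displacements(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative texture displacement per frame for (left, right) sheets."""
    vL, vR = spec.speed_left, spec.speed_right
    tc = spec.gap_width / (vL + vR)  # real-valued contact time
    t = np.arange(spec.n_frames, dtype=float)
    if spec.scenario == "stable_boundary":
        dL = vL * np.minimum(t, tc)
        dR = -vR * np.minimum(t, tc)
    elif spec.scenario == "push_through":
        dL = vL * t
        dR = -vR * np.minimum(t, tc) + vL * np.maximum(t - tc, 0.0)
    else:  # coalesce: brief interpenetration, then rest
        t_stop = tc + spec.coalesce_overlap / (vL + vR)
        dL = vL * np.minimum(t, t_stop)
        dR = -vR * np.minimum(t, t_stop)
    return dL, dR, tc


def render_two_sheet_video(spec: ScenarioSpec) -> tuple[VideoStack, GroundTruth]:
    """Render a two-channel gap-closure video with analytic ground truth.

    Channel 0 is the left (red) sheet, channel 1 the right (green) sheet.
    With gap 200 px and both speeds 4 px/frame the sheets touch at frame
    200 / (4 + 4) = 25.
    """
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    tex_red = _blob_texture((H, W), spec.grain, rng)
    tex_green = _blob_texture((H, W), spec.grain, rng)
    # faint static background structure (camera fixed pattern, autofluorescence);
    # real backgrounds are dark but not featureless
    bg_red = spec.background_amp * _smooth_field((H, W), rng)
    bg_green = spec.background_amp * _smooth_field((H, W), rng)
    dL, dR, tc = _sheet_displacements(spec)
    closure_frame = int(np.ceil(tc))

    xL0 = (W - spec.gap_width) / 2.0 - 1.0
    xR0 = (W + spec.gap_width) / 2.0
    contact_x = xL0 + spec.speed_left * tc

    left_front = xL0 + dL
    if spec.scenario == "push_through":
        right_front = np.where(
            np.arange(spec.n_frames) <= tc,
            xR0 + dR,
            contact_x + spec.speed_left * np.maximum(np.arange(spec.n_frames) - tc, 0.0),
        )
    else:
        right_front = xR0 + dR
    # fronts cannot pass each other except during scripted interpenetration
    if spec.scenario == "stable_boundary":
        left_front = np.minimum(left_front, right_front)

    boundary_x = np.where(
        np.arange(spec.n_frames) >= closure_frame,
        np.minimum((left_front + right_front) / 2.0, W - 1.0),
        (left_front + right_front) / 2.0,
    )

    cols = np.arange(W)
    frames = np.empty((spec.n_frames, H, W, 2), dtype=np.uint8)
    for t in range(spec.n_frames):
        red_tex = nd_shift(tex_red, (0.0, dL[t]), order=1, mode="grid-wrap")
        green_tex = nd_shift(tex_green, (0.0, dR[t]), order=1, mode="grid-wrap")
        mask_red = (cols <= left_front[t])[None, :]
        mask_green = (cols >= right_front[t])[None, :]
        # dye fills the cells, so the sheet interior floor (100) sits well
        # above the dark background; blobs modulate on top of it
        red = bg_red + (100.0 + 130.0 * red_tex) * mask_red
        green = bg_green + (100.0 + 130.0 * green_tex) * mask_green
        if spec.noise_sigma > 0:
            red = red + rng.normal(0, spec.noise_sigma, size=(H, W))
            green = green + rng.normal(0, spec.noise_sigma, size=(H, W))
        frames[t, ..., 0] = np.clip(red, 0, 255).astype(np.uint8)
        frames[t, ..., 1] = np.clip(green, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        closure_frame=closure_frame,
        boundary_x=boundary_x,
        left_front=left_front,
        right_front=right_front,
    )
    return VideoStack(frames=frames), truth


# ---------------------------------------------------------------------------
# saliency fixtures


def make_saliency_fixture(
    kind: str,
    shape: tuple[int, int] = (240, 240),
    n_regions: int = 144,
    high: float = 10.0,
) -> SaliencyMap:
    """Analytic saliency maps exercising the boundary-formation semantics.

    * ``constant`` — uniform map: uniformly distributed motion, index 0;
    * ``line`` — one column of regions at ``high`` over a zero background:
      motion concentrated on a line, index 1;
    * ``point`` — a single region at ``high``: point attractor, index 1;
    * ``multi_spot`` — two separated Gaussian-profile hotspots carrying the
      same total mass as the line fixture; the graded tails pull the Otsu
      'low' class above zero, so the index drops below the line's.
    """
    grid = make_superpixel_grid(shape[0], shape[1], n_regions)
    n = grid.n_superpixels
    cx = grid.centroids[:, 0]
    cy = grid.centroids[:, 1]
    ux = np.unique(cx)
    vals = np.zeros(n)
    mid_col = ux[len(ux) // 2]
    line_members = np.isclose(cx, mid_col)
    if kind == "constant":
        vals[:] = high
    elif kind == "line":
        vals[line_members] = high
    elif kind == "point":
        i = np.argmin((cx - shape[1] / 2) ** 2 + (cy - shape[0] / 2) ** 2)
        vals[i] = high
    elif kind == "multi_spot":
        sigma = 1.5 * grid.avg_width
        centers = [
            (shape[1] / 2, shape[0] / 3),
            (shape[1] / 2, 2 * shape[0] / 3),
        ]
        for mx, my in centers:
            d2 = (cx - mx) ** 2 + (cy - my) ** 2
            vals += np.exp(-d2 / (2 * sigma**2))
        vals *= high * line_members.sum() / vals.sum()  # equal total mass to 'line'
    else:
        raise InvalidArgumentError(f"unknown fixture kind {kind!r}")
    return SaliencyMap(
        values=vals[grid.labels],
        region_values=vals,
        direction="forward",
        radius_factor=None,
    )
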