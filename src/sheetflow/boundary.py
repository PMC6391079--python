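"""Intensity-based sheet segmentation, gap-closure detection and boundary
descriptors.

The track-free half of the analysis: each colour channel is segmented into
a binary sheet mask per frame, migrating fronts are extracted with a
horizontal sweepline, and the mean front-to-front distance over time gives
a gap curve whose floor marks the closure frame.  After closure, the
red/green interface is located either from mask intersections or from
matched opposing superpixel tracks, and summarised by displacement,
infiltration, shape and intermixing statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import InterpolatedUnivariateSpline, UnivariateSpline
from scipy.ndimage import binary_fill_holes, median_filter
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree
from skimage.filters import rank, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as morph_closing, disk
from skimage.restoration import denoise_bilateral
from skimage.util import img_as_ubyte
from sklearn.cluster import KMeans

from .exceptions import DegenerateInputError, InvalidArgumentError
from .measures import SaliencyMap, boundary_formation_index  # noqa: F401  (re-export convenience)
from .tracking import TrackArray

__all__ = [
    "BoundaryLine",
    "GapCurve",
    "segment_sheet_frame",
    "sweepline_fronts",
    "gap_distance_curve",
    "asymmetric_least_squares",
    "gap_closure_frame",
    "boundary_displacement",
    "boundary_line_from_masks",
    "boundary_line_from_tracks",
    "infiltration_fraction",
    "boundary_shape_index",
    "intermixing_coefficients",
    "velocity_kymograph",
]


@dataclass
class BoundaryLine:
    """Interface line: one x per unique y, plus a fitted spline x(y)."""

    y: np.ndarray
    x: np.ndarray
    frame: int | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        order = np.argsort(self.y)
        self.y = self.y[order]
        self.x = self.x[order]
        if len(self.y) >= 2:
            k = min(3, len(self.y) - 1)
            self._spline = InterpolatedUnivariateSpline(self.y, self.x, k=k)
        else:
            self._spline = None

    def __call__(self, y: np.ndarray) -> np.ndarray:
        """Interpolated boundary x at arbitrary y."""
        if self._spline is None:
            return np.full_like(np.asarray(y, dtype=float), self.x[0])
        return self._spline(y)

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class GapCurve:
    """Per-frame mean front-to-front distance (px)."""

    values: np.ndarray
    closure_frame: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# sheet segmentation


def _postprocess_mask(mask: np.ndarray, min_area_frac: float = 0.05) -> np.ndarray:
    """Binary closing, small-object removal, hole fill, largest component."""
    if not mask.any():
        return mask
    mask = morph_closing(mask, disk(5))
    min_area = max(int(min_area_frac * mask.size), 1)
    lab = cc_label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = (sizes >= min_area)[lab]
    if not mask.any():
        return mask
    mask = binary_fill_holes(mask)
    lab = cc_label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _fill_rows(mask: np.ndarray) -> np.ndarray:
    """Row-wise raster fill: set everything between the first and last mask
    pixel of each row (the sheets span rows, so row spans close holes)."""
    out = mask.copy()
    for r in range(mask.shape[0]):
        cols = np.flatnonzero(mask[r])
        if len(cols) >= 2:
            out[r, cols[0] : cols[-1] + 1] = True
    return out


def segment_sheet_frame(
    channel_image: np.ndarray,
    strategy: str = "kmeans",
    k: int = 2,
    avg_width: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Binary sheet mask from one channel of one frame.

    ``kmeans``: median filter (square kernel of the average superpixel
    width) then k-means on pixel intensities keeping all classes brighter
    than the darkest (k = 3 accommodates dim leading-edge cells), followed
    by morphological cleanup.  ``entropy``: edge-preserving smoothing, a
    local-entropy transform (texture, not brightness, marks cell-covered
    area), Otsu thresholding and row-raster hole filling.  A blank image
    yields an empty mask.
    """
    img = np.asarray(channel_image, dtype=float)
    if img.ndim != 2:
        raise InvalidArgumentError("expected a single-channel 2-D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    if strategy == "kmeans":
        smooth = median_filter(img, size=max(int(avg_width), 1))
        vals = smooth.reshape(-1, 1)
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(
            vals[:: max(1, vals.size // 20000)]
        )
        order = np.argsort(km.cluster_centers_.ravel())
        labels = km.predict(vals).reshape(img.shape)
        darkest = order[0]
        mask = labels != darkest
        return _postprocess_mask(mask)
    if strategy == "entropy":
        lo, hi = img.min(), img.max()
        norm = (img - lo) / (hi - lo)
        smooth = denoise_bilateral(norm, sigma_spatial=2)
        ent = rank.entropy(img_as_ubyte(smooth), disk(5))
        thr = threshold_otsu(ent)
        mask = ent > thr
        mask = _fill_rows(mask)
        if not mask.any():
            return mask
        lab = cc_label(mask)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        return lab == sizes.argmax()
    raise InvalidArgumentError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# fronts and gap closure


def sweepline_fronts(
    mask: np.ndarray, direction: str = "right", n_strips: int = 100
) -> np.ndarray:
    """Front points (x, y) of a sheet mask, one per horizontal strip.

    The frame is divided into ``n_strips`` horizontal strips; within each,
    the front is the mask pixel with the largest x if the sheet is moving
    right, the smallest x if moving left.  Strips without mask pixels
    contribute no point.
    """
    if direction not in ("left", "right"):
        raise InvalidArgumentError("direction must be 'left' or 'right'")
    if n_strips < 1:
        raise InvalidArgumentError("n_strips must be >= 1")
    H = mask.shape[0]
    edges = np.linspace(0, H, n_strips + 1).round().astype(int)
    points = []
    for s in range(n_strips):
        rows = mask[edges[s] : edges[s + 1]]
        rr, cc = np.nonzero(rows)
        if len(cc) == 0:
            continue
        pick = cc.argmax() if direction == "right" else cc.argmin()
        points.append((cc[pick], edges[s] + rr[pick]))
    return np.asarray(points, dtype=float).reshape(-1, 2)


def gap_distance_curve(
    masks_red: np.ndarray,
    masks_green: np.ndarray,
    n_strips: int = 100,
    directions: tuple[str, str] = ("right", "left"),
) -> GapCurve:
    """Mean front-to-front distance per frame.

    Each red front point is paired with the nearest green front point by
    Euclidean distance; the per-frame value is the mean pair distance.
    Defaults assume the red sheet moves right and the green sheet left.
    """
    T = len(masks_red)
    if len(masks_green) != T:
        raise InvalidArgumentError("mask stacks must share length")
    values = np.zeros(T)
    for t in range(T):
        fr = sweepline_fronts(masks_red[t], directions[0], n_strips)
        fg = sweepline_fronts(masks_green[t], directions[1], n_strips)
        if len(fr) == 0 or len(fg) == 0:
            values[t] = np.nan
            continue
        tree = cKDTree(fg)
        d, _ = tree.query(fr)
        values[t] = d.mean()
    return GapCurve(values=values)


def asymmetric_least_squares(
    y: np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
    diff_order: int = 1,
) -> np.ndarray:
    """Whittaker-smoother baseline with asymmetric weights.

    Points above the baseline are down-weighted by ``p``, points below by
    ``1 - p``, so the fit hugs the lower envelope.  ``lam`` penalises the
    squared difference of order ``diff_order``: order 1 (slope penalty)
    drives the baseline towards a flat floor, which is the behaviour wanted
    for gap curves whose post-closure level estimates the segmentation
    error; order 2 gives the classic stiff-curve baseline.
    """
    y = np.asarray(y, dtype=float)
    L = len(y)
    if diff_order == 1:
        D = sp.diags([1.0, -1.0], [0, 1], shape=(L - 1, L))
    elif diff_order == 2:
        D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(L - 2, L))
    else:
        raise InvalidArgumentError("diff_order must be 1 or 2")
    DTD = lam * (D.T @ D)
    w = np.ones(L)
    z = y.copy()
    for _ in range(n_iter):
        W = sp.diags(w)
        z = spsolve((W + DTD).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def _noise_sigma(y: np.ndarray) -> float:
    """Robust white-noise scale from first differences (MAD estimator)."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def gap_closure_frame(
    curve: GapCurve | np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
    spline_smooth: float | None = None,
    min_snr: float = 10.0,
) -> int | None:
    """First frame at which the gap curve reaches its baseline floor.

    An asymmetric-least-squares baseline (slope-penalised, hugging the
    lower envelope) captures the residual front distance due to
    segmentation error; a smoothing linear spline approximates the curve
    itself, with its smoothing chosen from a difference-based robust noise
    estimate (``spline_smooth`` overrides, in spline residual units).
    Closure is the first frame where the spline drops below
    baseline + 2 noise scales, required to have first exceeded that
    threshold ("armed").  A curve whose excursion above the floor never
    reaches ``min_snr`` noise scales carries no resolvable open gap —
    constant or never-closing curves — and yields None.
    """
    values = curve.values if isinstance(curve, GapCurve) else np.asarray(curve, float)
    finite = np.isfinite(values)
    if finite.sum() < 10:
        raise InvalidArgumentError("gap curve too short (need >= 10 finite frames)")
    t = np.arange(len(values), dtype=float)
    tv, yv = t[finite], values[finite]
    baseline = asymmetric_least_squares(yv, lam=lam, p=p, n_iter=n_iter)
    sigma = _noise_sigma(yv)
    s = len(yv) * sigma**2 if spline_smooth is None else spline_smooth
    spl = UnivariateSpline(tv, yv, k=1, s=s)
    fitted = spl(tv)
    # the baseline is smooth, so its own std understates the measurement
    # noise; the cut allows two noise scales above the floor
    cut = baseline + 2.0 * max(baseline.std(), sigma)
    floor = float(np.median(baseline))
    amplitude = float(fitted.max() - floor)
    if sigma > 0:
        if amplitude < min_snr * sigma:
            return None
    elif amplitude <= 2.0 * baseline.std():
        return None
    armed = fitted >= cut + 2.0 * sigma
    if not armed.any():
        return None
    start = int(np.argmax(armed))
    below = fitted < cut
    below[: start + 1] = False
    if not below.any():
        return None
    return int(tv[np.argmax(below)])


def boundary_displacement(
    mean_x_closure: float, mean_x_final: float, width: float
) -> float:
    """Post-closure interface drift normalised by image width.

    |mean x at the final frame - mean x at the closure frame| / width.
    """
    if width <= 0:
        raise InvalidArgumentError("width must be positive")
    return float(abs(mean_x_final - mean_x_closure) / width)


# ---------------------------------------------------------------------------
# boundary lines


def _line_from_points(x: np.ndarray, y: np.ndarray, frame: int | None) -> BoundaryLine:
    """Average x per unique y, then fit the interpolating spline."""
    uy, inv = np.unique(y, return_inverse=True)
    sums = np.bincount(inv, weights=x)
    counts = np.bincount(inv)
    return BoundaryLine(y=uy, x=sums / counts, frame=frame)


def boundary_line_from_masks(
    mask_red: np.ndarray, mask_green: np.ndarray, frame: int | None = None
) -> BoundaryLine | None:
    """Boundary line from the set intersection of the two sheet masks.

    Returns None when the masks do not overlap (no boundary yet).
    """
    inter = mask_red & mask_green
    if not inter.any():
        return None
    rr, cc = np.nonzero(inter)
    return _line_from_points(cc.astype(float), rr.astype(float), frame)


def boundary_line_from_tracks(
    tracks_red: TrackArray,
    tracks_green: TrackArray,
    frame: int,
    avg_width: float,
    move_thresh: float | None = None,
    match_radius: float | None = None,
    min_neighbours: int = 5,
    density_radius: float | None = None,
) -> BoundaryLine | None:
    """Boundary line from matched opposing superpixel tracks at ``frame``.

    Candidates are red/green superpixels that moved since the previous
    frame and have at least one opposite-colour superpixel within
    ``match_radius`` (default 2 average widths); sparse outliers are
    removed by requiring ``min_neighbours`` candidates within
    ``density_radius`` (default 3 average widths).  Tracks whose total path
    length is below ``move_thresh`` (default 5 average widths) never
    qualify.  Returns None if no matches survive.
    """
    if frame < 1:
        raise InvalidArgumentError("frame must be >= 1 (needs a previous frame)")
    move_thresh = 5.0 * avg_width if move_thresh is None else move_thresh
    match_radius = 2.0 * avg_width if match_radius is None else match_radius
    density_radius = 3.0 * avg_width if density_radius is None else density_radius

    def _candidates(tr: TrackArray) -> np.ndarray:
        total = tr.path_length()
        stepped = (
            np.linalg.norm(tr.positions[:, frame] - tr.positions[:, frame - 1], axis=1)
            > 0
        )
        return np.flatnonzero((total > move_thresh) & stepped)

    ired = _candidates(tracks_red)
    igreen = _candidates(tracks_green)
    if len(ired) == 0 or len(igreen) == 0:
        return None
    pr = tracks_red.positions[ired, frame]
    pg = tracks_green.positions[igreen, frame]
    tr_green = cKDTree(pg)
    tr_red = cKDTree(pr)
    d_rg, _ = tr_green.query(pr)
    d_gr, _ = tr_red.query(pg)
    pts = np.vstack([pr[d_rg <= match_radius], pg[d_gr <= match_radius]])
    if len(pts) == 0:
        return None
    # density filter: keep points with enough fellow candidates nearby
    tree = cKDTree(pts)
    counts = np.asarray([len(c) for c in tree.query_ball_point(pts, density_radius)])
    keep = counts >= min_neighbours  # includes self
    if not keep.any():
        return None
    pts = pts[keep]
    return _line_from_points(pts[:, 0], pts[:, 1], frame)


def infiltration_fraction(
    points: np.ndarray, line: BoundaryLine, invading_side: str = "right"
) -> float:
    """Fraction of points lying beyond the boundary line.

    ``invading_side`` names the side of the line occupied by the *other*
    sheet: "right" counts points with x strictly greater than the line's x
    at their y; points exactly on the line count as non-invading.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise DegenerateInputError("empty point set")
    if invading_side not in ("left", "right"):
        raise InvalidArgumentError("invading_side must be 'left' or 'right'")
    line_x = line(pts[:, 1])
    # small tolerance so points numerically on the line never count as across
    if invading_side == "right":
        across = pts[:, 0] > line_x + 1e-9
    else:
        across = pts[:, 0] < line_x - 1e-9
    return float(across.mean())


def boundary_shape_index(line: BoundaryLine) -> float:
    """Boundary tortuosity: arc length / straight chord length, >= 1."""
    if len(line) < 2:
        raise DegenerateInputError("need at least 2 boundary samples")
    pts = np.column_stack([line.x, line.y])
    seg = np.diff(pts, axis=0)
    arc = np.linalg.norm(seg, axis=1).sum()
    chord = np.linalg.norm(pts[-1] - pts[0])
    if chord == 0:
        raise DegenerateInputError("degenerate boundary (zero chord)")
    return float(arc / chord)


def intermixing_coefficients(
    boundary_mask: np.ndarray,
    saliency_map: SaliencyMap | np.ndarray,
    thresh: float | None = None,
) -> tuple[float, float]:
    """(image, motion) intermixing coefficients, both area fractions.

    The image coefficient is the boundary-mask area over the frame area — a
    static measure of how spread-out the overlap zone is.  The motion
    coefficient thresholds the motion saliency map (Otsu by default) and
    reports the above-threshold area fraction; the two agree when a stable
    boundary forms with coordinated motion, and diverge when the interface
    is dynamic.
    """
    bm = np.asarray(boundary_mask, dtype=bool)
    image_coeff = float(bm.mean())
    vals = (
        saliency_map.values
        if isinstance(saliency_map, SaliencyMap)
        else np.asarray(saliency_map, dtype=float)
    )
    if np.allclose(vals, vals.flat[0]):
        return image_coeff, 0.0
    thr = threshold_otsu(vals) if thresh is None else thresh
    motion_coeff = float((vals > thr).mean())
    return image_coeff, motion_coeff


# ---------------------------------------------------------------------------
# kymographs


def velocity_kymograph(
    source: TrackArray | np.ndarray,
    width: float | None = None,
    n_bins: int | None = None,
) -> np.ndarray:
    """Kymograph of median x-velocity vs x-position, one row per frame pair.

    From a TrackArray the superpixel x-velocities are binned by current
    x-position; ``n_bins`` defaults to twice the number of unique frame-0
    centroid columns (Nyquist for the grid sampling).  From a (T-1, H, W, 2)
    flow-field stack the per-pixel dx values are binned by column.
    """
    if isinstance(source, TrackArray):
        pos = source.positions
        vel = source.velocities()
        if n_bins is None:
            n_bins = 2 * len(np.unique(pos[:, 0, 0]))
        if width is None:
            width = float(pos[..., 0].max()) + 1.0
        edges = np.linspace(0, width, n_bins + 1)
        Tm1 = vel.shape[1]
        out = np.full((Tm1, n_bins), np.nan)
        for t in range(Tm1):
            which = np.clip(np.searchsorted(edges, pos[:, t, 0], side="right") - 1, 0, n_bins - 1)
            for b in np.unique(which):
                out[t, b] = np.median(vel[which == b, t, 0])
        return out
    flows = np.asarray(source, dtype=float)
    if flows.ndim != 4 or flows.shape[-1] != 2:
        raise InvalidArgumentError("flow source must be (T-1, H, W, 2)")
    W = flows.shape[2]
    if n_bins is None:
        n_bins = W
    edges = np.linspace(0, W, n_bins + 1).round().astype(int)
    out = np.empty((flows.shape[0], n_bins))
    for t in range(flows.shape[0]):
        for b in range(n_bins):
            out[t, b] = np.median(flows[t, :, edges[b] : edges[b + 1], 0])
    return out
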