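"""Track- and mesh-derived motion statistics.

Everything in this module consumes the ``(n, T, 2)`` track representation
plus, where relevant, a mesh.  The statistics fall into four families:

* mesh distortion: strain curves, the mesh stability index, mesh order;
* single-track kinematics: MSD with power-law exponent, RMSD;
* pairwise coupling: spatial velocity correlation with exponential-decay
  fit, normalized velocity cross-correlation (VCC) with lag search;
* spatial localisation: motion saliency maps and the boundary formation
  index derived from them.

All of the mesh statistics are invariant under adding a common drift to
every track, which is what makes them usable on microscope stages with
slow positional drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, InvalidArgumentError
from .meshes import MeshStatic, build_radius_graph, mesh_strain_vector
from .tracking import SuperpixelGrid, TrackArray

__all__ = [
    "StrainCurve",
    "SaliencyMap",
    "mesh_strain_curve",
    "combine_channel_curves",
    "normalize_strain_curve",
    "mesh_stability_index",
    "velocity_order",
    "mesh_order",
    "msd",
    "fit_msd_exponent",
    "rmsd",
    "spatial_correlation",
    "velocity_cross_correlation",
    "normalized_vcc",
    "sheet_vcc",
    "motion_saliency_map",
    "boundary_formation_index",
]

#: below this norm a vector counts as non-moving and is excluded from
#: order parameters
MOVING_EPS = 1e-8


@dataclass
class StrainCurve:
    """Per-frame mean mesh strain (pixels); ``values[0] == 0`` by construction."""

    values: np.ndarray
    normalized: bool = False
    norm_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SaliencyMap:
    """Image-shaped accumulation of radius-graph node degrees.

    ``values`` is the frame-shaped map after spatial averaging over the
    frame-0 superpixel partition; ``region_values`` holds one value per
    superpixel region (the representation the boundary formation index is
    computed on).
    """

    values: np.ndarray
    region_values: np.ndarray
    direction: str = "forward"
    radius_factor: float | None = None


# ---------------------------------------------------------------------------
# mesh strain


def mesh_strain_curve(tracks: TrackArray, mesh: MeshStatic) -> StrainCurve:
    """Mean mesh strain per frame.

    Per superpixel, strain at frame t is the mean absolute change of its
    Euclidean distances to mesh neighbours relative to frame 0 (an L1
    statistic, deliberately robust to occasional flow errors):

        eps_i(t) = (1/|N_i|) sum_{j in N_i} | d_ij(t) - d_ij(0) |

    The curve is eps_i(t) averaged over all non-isolated superpixels.
    """
    edges = mesh.edge_list()
    T = tracks.n_frames
    values = np.zeros(T)
    if len(edges) == 0:
        return StrainCurve(values=values)
    pos = tracks.positions  # (n, T, 2)
    diff = pos[edges[:, 0]] - pos[edges[:, 1]]  # (E, T, 2)
    dist = np.linalg.norm(diff, axis=2)  # (E, T)
    abs_change = np.abs(dist - dist[:, :1])  # (E, T)
    n = tracks.n_tracks
    deg = mesh.degrees().astype(float)
    acc = np.zeros((n, T))
    np.add.at(acc, edges[:, 0], abs_change)
    np.add.at(acc, edges[:, 1], abs_change)
    active = deg > 0
    eps = acc[active] / deg[active, None]
    values = eps.mean(axis=0)
    values[0] = 0.0
    return StrainCurve(values=values)


def combine_channel_curves(curves: Sequence[StrainCurve]) -> StrainCurve:
    """Unweighted mean of per-channel strain curves (multi-channel videos)."""
    if not curves:
        raise InvalidArgumentError("no curves to combine")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise InvalidArgumentError("channel curves have different lengths")
    return StrainCurve(values=np.mean([c.values for c in curves], axis=0))


def normalize_strain_curve(
    curve: StrainCurve, window: tuple[int, int] | None = None
) -> StrainCurve:
    """Divide by the maximum strain within ``window`` (default: whole curve).

    An identically-zero curve (rigid or static motion) maps to an
    identically-zero normalized curve rather than 0/0.
    """
    values = curve.values
    if window is None:
        window = (0, len(values))
    lo, hi = window
    if not (0 <= lo < hi <= len(values)):
        raise InvalidArgumentError(f"window {window} out of range for length {len(values)}")
    m = values[lo:hi].max()
    if m <= 0:
        return StrainCurve(values=np.zeros_like(values), normalized=True, norm_window=window)
    return StrainCurve(values=values / m, normalized=True, norm_window=window)


def mesh_stability_index(norm_curve: StrainCurve, tail: int | None = None) -> float:
    """1 minus the end gradient of the normalized strain curve on unit time.

    Time is rescaled to [0, 1] so videos of different length are comparable;
    the end gradient is the mean first-order difference over the last
    ``tail`` frames divided by the normalized step 1/(T-1).  A plateaued
    curve scores 1 (maximally stable); a straight rise from 0 to 1 scores 0.
    ``tail`` defaults to max(10, ceil(0.1 T)).
    """
    values = norm_curve.values
    T = len(values)
    if T < 2:
        raise InvalidArgumentError("curve too short")
    if tail is None:
        tail = max(10, int(np.ceil(0.1 * T)))
        tail = min(tail, T - 1)
    if not (1 <= tail <= T - 1):
        raise InvalidArgumentError(f"tail must be in [1, {T - 1}]; got {tail}")
    diffs = np.diff(values)[-tail:]
    end_gradient = diffs.mean() * (T - 1)
    return float(1.0 - end_gradient)


# ---------------------------------------------------------------------------
# order parameters


def _resultant_order(vectors: np.ndarray, zero_value: float | None) -> float:
    """Mean-resultant-length of unit vectors; near-zero vectors excluded."""
    norms = np.linalg.norm(vectors, axis=1)
    moving = norms > MOVING_EPS
    if not moving.any():
        return np.nan if zero_value is None else zero_value
    unit = vectors[moving] / norms[moving, None]
    return float(min(np.linalg.norm(unit.mean(axis=0)), 1.0))


def velocity_order(tracks: TrackArray, t: int) -> float:
    """Polar order parameter of instantaneous velocities at frame ``t``.

    psi(t) = | mean_i V_i(t)/|V_i(t)| | over superpixels moving at t;
    1 for perfectly aligned motion, ~n^-1/2 for isotropic random headings.
    NaN if nothing moves (the order of no motion is undefined).
    """
    if not (0 <= t < tracks.n_frames - 1):
        raise InvalidArgumentError(f"t must be in [0, {tracks.n_frames - 2}]")
    v = tracks.positions[:, t + 1] - tracks.positions[:, t]
    return _resultant_order(v, zero_value=None)


def mesh_order(tracks: TrackArray, mesh: MeshStatic) -> tuple[np.ndarray, float]:
    """Order parameter of resultant mesh strain vectors, per frame + mean.

    Identical in form to the velocity order parameter but computed on mesh
    strain vectors, which are stable under rigid collective drift: a frame
    in which every strain vector vanishes (perfectly rigid motion) is
    maximally ordered and scores 1.
    """
    T = tracks.n_frames
    series = np.empty(T - 1)
    for t in range(1, T):
        vec = mesh_strain_vector(tracks, mesh, t)
        series[t - 1] = _resultant_order(vec, zero_value=1.0)
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# MSD / RMSD


def msd(tracks: TrackArray, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared displacement vs time lag.

    MSD(dt) = < |r_i(t+dt) - r_i(t)|^2 > averaged over all start times t and
    all tracks.  Returns (lags, msd) with lags 1..max_lag.
    """
    T = tracks.n_frames
    if T < 2:
        raise InvalidArgumentError("need at least 2 frames")
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    pos = tracks.positions
    lags = np.arange(1, max_lag + 1)
    out = np.empty(max_lag)
    for k, lag in enumerate(lags):
        d = pos[:, lag:] - pos[:, :-lag]
        out[k] = np.mean(np.sum(d * d, axis=2))
    return lags, out


def fit_msd_exponent(
    lags: np.ndarray,
    msd_values: np.ndarray,
    fit_range: int | None = None,
) -> float:
    """Power-law exponent alpha of MSD ~ dt^alpha by log-log least squares.

    Fitted over the first ``fit_range`` lags (default: max(3, 10% of lags)).
    alpha = 1 is uncorrelated Brownian motion, alpha = 2 ballistic.
    """
    lags = np.asarray(lags, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    if fit_range is None:
        fit_range = max(3, len(lags) // 10)
    fit_range = min(fit_range, len(lags))
    if fit_range < 2:
        raise InvalidArgumentError("need at least 2 lags to fit")
    x = lags[:fit_range]
    y = msd_values[:fit_range]
    if np.any(y <= 0):
        raise DegenerateInputError("MSD is zero over the fit range; exponent undefined")
    slope, _ = np.polyfit(np.log(x), np.log(y), 1)
    return float(slope)


def rmsd(
    tracks: TrackArray,
    normalize: bool = False,
    ref_frame: int | None = None,
) -> np.ndarray:
    """Root mean squared displacement from the initial position, per frame.

    RMSD(t) = sqrt( < |r_i(t) - r_i(0)|^2 >_i ).  With ``normalize`` the
    curve is divided by its maximum, or by its value at ``ref_frame`` when
    given (useful to compare videos of different duration at a shared
    timepoint).
    """
    pos = tracks.positions
    d = pos - pos[:, :1]
    curve = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))
    if normalize:
        ref = curve[ref_frame] if ref_frame is not None else curve.max()
        if ref > 0:
            curve = curve / ref
    return curve


# ---------------------------------------------------------------------------
# velocity correlations


def _centered_velocities(tracks: TrackArray) -> tuple[np.ndarray, np.ndarray]:
    """Velocities centred per track, plus total (2-component) std per track."""
    v = tracks.velocities()  # (n, T-1, 2)
    vc = v - v.mean(axis=1, keepdims=True)
    sig = np.sqrt(np.mean(np.sum(vc * vc, axis=2), axis=1))  # population
    return vc, sig


def spatial_correlation(
    tracks: TrackArray,
    radii: Sequence[float],
    avg_width: float,
    fit: bool = True,
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Mean neighbour velocity correlation as a function of radius.

    For each radius r (in multiples of ``avg_width``) the neighbourhood N_i
    holds all superpixels within r * avg_width of i's frame-0 centroid.
    The statistic is the mean over i of the mean temporal correlation of
    velocity series with each neighbour, where the 2-D covariance sums both
    components and is normalized by total standard deviations.  The decay
    with r is fitted to ``a * exp(-r/b)``; returns (correlations, (a, b)).
    """
    radii = np.asarray(radii, dtype=float)
    if tracks.n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    if np.any(np.diff(radii) < 0):
        raise InvalidArgumentError("radii must be sorted ascending")
    vc, sig = _centered_velocities(tracks)
    Tm1 = vc.shape[1]
    pos0 = tracks.positions[:, 0]
    tree = cKDTree(pos0)
    valid = sig > 0
    out = np.full(len(radii), np.nan)
    for k, r in enumerate(radii):
        pairs = tree.query_pairs(r * avg_width, output_type="ndarray")
        per_node: dict[int, list[float]] = {}
        for i, j in pairs:
            if not (valid[i] and valid[j]):
                continue
            cov = np.mean(np.sum(vc[i] * vc[j], axis=1))
            c = cov / (sig[i] * sig[j])
            per_node.setdefault(i, []).append(c)
            per_node.setdefault(j, []).append(c)
        if per_node:
            out[k] = np.mean([np.mean(v) for v in per_node.values()])
        else:
            out[k] = 0.0
    params = None
    if fit:
        try:
            popt, _ = curve_fit(
                lambda x, a, b: a * np.exp(-x / b),
                radii,
                out,
                p0=(max(out[0], 0.1), max(radii.mean(), 1.0)),
                bounds=([-2, 1e-6], [2, 1e6]),
                maxfev=10000,
            )
            params = (float(popt[0]), float(popt[1]))
        except (RuntimeError, ValueError):
            params = None
    return out, params


def normalized_vcc(vel_i: np.ndarray, vel_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of two 2-D velocity series over all lags.

    Each series is standardized as Vhat = (V - mean) / sigma with sigma the
    total 2-component standard deviation; then

        C(m) = (1/T) sum_t Vhat_i(t+m) . Vhat_j(t)

    with zero padding outside the series.  |C(m)| <= 1 (Cauchy-Schwarz) and
    self-correlation at zero lag is exactly 1 under this normalization.
    Returns (lags, C) with lags from -(T-1) to (T-1).
    """
    vi = np.asarray(vel_i, dtype=float)
    vj = np.asarray(vel_j, dtype=float)
    if vi.ndim != 2 or vi.shape[1] != 2 or vj.ndim != 2 or vj.shape[1] != 2:
        raise InvalidArgumentError("velocity series must be (T, 2)")
    if len(vi) != len(vj) or len(vi) < 2:
        raise InvalidArgumentError("series must share a length >= 2")
    T = len(vi)
    vic = vi - vi.mean(axis=0)
    vjc = vj - vj.mean(axis=0)
    si = np.sqrt(np.mean(np.sum(vic * vic, axis=1)))
    sj = np.sqrt(np.mean(np.sum(vjc * vjc, axis=1)))
    if si == 0 or sj == 0:
        raise DegenerateInputError("zero-variance velocity series: VCC undefined")
    vih = vic / si
    vjh = vjc / sj
    corr = (
        np.correlate(vih[:, 0], vjh[:, 0], mode="full")
        + np.correlate(vih[:, 1], vjh[:, 1], mode="full")
    ) / T
    lags = np.arange(-(T - 1), T)
    return lags, corr


def velocity_cross_correlation(
    track_i: TrackArray | np.ndarray,
    track_j: TrackArray | np.ndarray,
) -> float:
    """Max absolute normalized velocity cross-correlation over all lags.

    Accepts single-track position arrays (T, 2) (velocities are taken
    internally) or raw velocity series.  The scalar lies in [0, 1]; 1 means
    the two velocity histories coincide up to scaling at some time delay.
    """
    vi = _as_velocity_series(track_i)
    vj = _as_velocity_series(track_j)
    _, corr = normalized_vcc(vi, vj)
    return float(np.max(np.abs(corr)))


def _as_velocity_series(track) -> np.ndarray:
    if isinstance(track, TrackArray):
        if track.n_tracks != 1:
            raise InvalidArgumentError("expected a single track")
        return track.velocities()[0]
    arr = np.asarray(track, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return np.diff(arr, axis=0)
    raise InvalidArgumentError("track must be (T, 2) positions or TrackArray")


def sheet_vcc(
    tracks_red: TrackArray,
    tracks_green: TrackArray,
    closure_frame: int,
    offset: int = 5,
    max_pairs: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Average cross-sheet VCC before and after gap closure.

    Pairs every red with every green track (optionally a seeded random
    subsample of ``max_pairs`` pairings), computes the max-abs VCC of each
    pair separately on frames [0, closure-offset] and [closure+offset, T),
    and averages.  A rise from before to after is evidence that contact
    couples the two sheets' motion.  Zero-variance pairs are skipped.
    """
    T = tracks_red.n_frames
    before_end = closure_frame - offset
    after_start = closure_frame + offset
    if before_end < 2 or T - after_start < 2:
        raise InvalidArgumentError("closure too close to the video ends for the offset")
    pr = tracks_red.positions[:, : before_end + 1]
    pg = tracks_green.positions[:, : before_end + 1]
    pr2 = tracks_red.positions[:, after_start:]
    pg2 = tracks_green.positions[:, after_start:]
    pairs = [(i, j) for i in range(tracks_red.n_tracks) for j in range(tracks_green.n_tracks)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in idx]

    def _avg(a: np.ndarray, b: np.ndarray) -> float:
        vals = []
        for i, j in pairs:
            try:
                vals.append(velocity_cross_correlation(a[i], b[j]))
            except DegenerateInputError:
                continue
        if not vals:
            raise DegenerateInputError("no valid pairings (all series constant)")
        return float(np.mean(vals))

    return _avg(pr, pg), _avg(pr2, pg2)


# ---------------------------------------------------------------------------
# motion saliency


def motion_saliency_map(
    tracks: TrackArray,
    grid: SuperpixelGrid,
    radius_factor: float = 5.0,
    direction: str = "forward",
    frame_range: tuple[int, int] | None = None,
) -> SaliencyMap:
    """Long-time map of where motion concentrates.

    Per frame a radius-neighbour graph (radius = ``radius_factor`` x average
    superpixel width) is built on current positions and each superpixel's
    node degree is written into a blank image at its rounded position;
    the per-frame images are averaged over time and then spatially over the
    frame-0 superpixel partition.  Boundaries act as motion attractors —
    superpixels pile up against them — so persistent ridges mark motion
    sinks.  ``direction="backward"`` runs on time-reversed tracks, turning
    sinks into sources.
    """
    if direction not in ("forward", "backward"):
        raise InvalidArgumentError("direction must be 'forward' or 'backward'")
    H, W = grid.shape
    pos = tracks.positions
    if direction == "backward":
        pos = pos[:, ::-1]
    T = pos.shape[1]
    if frame_range is None:
        frame_range = (0, T)
    lo, hi = frame_range
    if not (0 <= lo < hi <= T):
        raise InvalidArgumentError(f"frame_range {frame_range} out of range")
    radius = radius_factor * grid.avg_width
    acc = np.zeros((H, W))
    for t in range(lo, hi):
        p = pos[:, t]
        adj = build_radius_graph(p, radius)
        deg = np.diff(adj.indptr)
        x = np.clip(np.rint(p[:, 0]).astype(int), 0, W - 1)
        y = np.clip(np.rint(p[:, 1]).astype(int), 0, H - 1)
        np.add.at(acc, (y, x), deg)
    acc /= hi - lo
    # spatial average over the frame-0 partition
    n = grid.n_superpixels
    sums = np.bincount(grid.labels.ravel(), weights=acc.ravel(), minlength=n)
    areas = np.bincount(grid.labels.ravel(), minlength=n)
    region_values = sums / np.maximum(areas, 1)
    values = region_values[grid.labels]
    return SaliencyMap(
        values=values,
        region_values=region_values,
        direction=direction,
        radius_factor=radius_factor,
    )


def boundary_formation_index(salmap: SaliencyMap | np.ndarray) -> float:
    """Otsu-split signal-to-noise ratio of the saliency map, in [0, 1].

    The region values are split into 'high' and 'low' classes by Otsu
    thresholding; the index is (mean(high) - mean(low)) / mean(high).
    Uniform motion scores 0; motion concentrated on a single line with an
    empty background scores 1; multiple diffuse hotspots score in between.
    A constant map (degenerate Otsu) scores 0 by definition.
    """
    if isinstance(salmap, SaliencyMap):
        vals = np.asarray(salmap.region_values, dtype=float)
    else:
        vals = np.asarray(salmap, dtype=float).ravel()
    if vals.size == 0 or np.allclose(vals, vals.flat[0]):
        return 0.0
    try:
        thr = threshold_otsu(vals)
    except ValueError:
        return 0.0
    high = vals[vals > thr]
    low = vals[vals <= thr]
    if high.size == 0 or low.size == 0:
        return 0.0
    mh = high.mean()
    if mh <= 0:
        return 0.0
    return float((mh - low.mean()) / mh)
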