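"""Motion signatures, 2-D motion maps, track clustering and control cut-offs.

A video's global motion pattern is summarised by its normalized mesh
strain curve resampled onto a common time window (the *motion signature*);
PCA over a cohort of signatures gives a 2-D *motion map* on which held-out
videos can be projected without refitting.  Within one video, superpixels
are grouped into motion phenotypes by fitting Gaussian mixtures to their
local strain curves, with BIC selecting the number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .exceptions import InvalidArgumentError
from .measures import StrainCurve, mesh_strain_curve, normalize_strain_curve
from .meshes import MeshStatic
from .tracking import TrackArray

__all__ = [
    "MotionSignature",
    "MotionMap",
    "motion_signature",
    "fit_motion_map",
    "project_signature",
    "local_strain_curves",
    "cluster_superpixel_tracks",
    "control_cutoff",
]


@dataclass
class MotionSignature:
    """Fixed-length normalized strain curve describing one video."""

    vector: np.ndarray
    video_id: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)


@dataclass
class MotionMap:
    """Learnt 2-D PCA embedding of a signature cohort."""

    components: np.ndarray  # (2, L), orthonormal rows
    mean: np.ndarray  # (L,)
    coords: np.ndarray  # (n_videos, 2)
    video_ids: list[str]


def motion_signature(
    curves: StrainCurve | list[StrainCurve],
    n_points: int = 97,
    window: tuple[int, int] | None = None,
    video_id: str = "",
) -> MotionSignature:
    """Normalized strain curve resampled to ``n_points`` samples.

    Multi-channel input is averaged (unweighted) before normalization.
    ``window`` restricts both the resampling range and the normalizing
    maximum to a common comparison window (e.g. the first 97 frames of
    hourly videos of unequal length); videos shorter than the window are an
    error.  The 97-point default matches one sample per hour over 0-96 h.
    """
    if isinstance(curves, StrainCurve):
        curves = [curves]
    values = np.mean([np.asarray(c.values, dtype=float) for c in curves], axis=0)
    T = len(values)
    if window is None:
        window = (0, T)
    lo, hi = window
    if not (0 <= lo < hi <= T):
        raise InvalidArgumentError(f"window {window} exceeds curve length {T}")
    seg = values[lo:hi]
    grid = np.linspace(0, len(seg) - 1, n_points)
    resampled = np.interp(grid, np.arange(len(seg)), seg)
    m = resampled.max()
    if m > 0:
        resampled = resampled / m
    return MotionSignature(vector=resampled, video_id=video_id)


def fit_motion_map(signatures: list[MotionSignature]) -> MotionMap:
    """PCA (2 components, no whitening) over a cohort of signatures."""
    if len(signatures) < 3:
        raise InvalidArgumentError("need at least 3 signatures to fit a map")
    lengths = {len(s.vector) for s in signatures}
    if len(lengths) != 1:
        raise InvalidArgumentError("signatures have inconsistent lengths")
    X = np.stack([s.vector for s in signatures])
    pca = PCA(n_components=2)
    coords = pca.fit_transform(X)
    return MotionMap(
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        coords=coords,
        video_ids=[s.video_id for s in signatures],
    )


def project_signature(motion_map: MotionMap, signature: MotionSignature) -> np.ndarray:
    """Project a (possibly held-out) signature onto a learnt map.

    The projection is affine in the signature, so convex combinations of
    signatures land on the segment between their projections; the training
    mean signature maps to the origin.
    """
    v = signature.vector
    if len(v) != len(motion_map.mean):
        raise InvalidArgumentError("signature length does not match the map")
    return (v - motion_map.mean) @ motion_map.components.T


def local_strain_curves(tracks: TrackArray, mesh: MeshStatic) -> np.ndarray:
    """Per-superpixel local mesh strain curves, shape (n, T).

    Row i is eps_i(t), the mean absolute change of i's neighbour distances
    from frame 0 — the feature matrix used for track clustering.  Isolated
    superpixels get all-zero rows.
    """
    edges = mesh.edge_list()
    n, T = tracks.n_tracks, tracks.n_frames
    acc = np.zeros((n, T))
    if len(edges):
        pos = tracks.positions
        diff = pos[edges[:, 0]] - pos[edges[:, 1]]
        dist = np.linalg.norm(diff, axis=2)
        change = np.abs(dist - dist[:, :1])
        np.add.at(acc, edges[:, 0], change)
        np.add.at(acc, edges[:, 1], change)
        deg = mesh.degrees().astype(float)
        acc[deg > 0] /= deg[deg > 0, None]
    return acc


def cluster_superpixel_tracks(
    tracks: TrackArray,
    mesh: MeshStatic,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 5,
    covariance_type: str = "tied",
) -> tuple[np.ndarray, int, np.ndarray]:
    """Cluster superpixels by their local strain dynamics.

    Gaussian mixtures with k = 1..k_max components are fitted to the
    (n, T) local strain-curve matrix; the k minimising BIC is selected.
    The default shared ("tied") covariance keeps the parameter count far
    below the sample count for typical curve lengths, so BIC responds to
    differences in mean curve shape — the motion phenotype — rather than
    over-splitting the skewed within-group strain distribution.
    Returns (labels, k_selected, posterior) with the (n, k) posterior
    responsibilities.
    """
    X = local_strain_curves(tracks, mesh)
    n = X.shape[0]
    if not (1 <= k_max < n):
        raise InvalidArgumentError(f"k_max must be in [1, {n - 1}]")
    best = None
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-4,
        ).fit(X)
        bic = gmm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, k, gmm)
    _, k_sel, gmm = best
    return gmm.predict(X), k_sel, gmm.predict_proba(X)


def control_cutoff(control_values, side: str = "above") -> float:
    """Decision threshold one sample SD from the pooled control mean.

    Under approximately normal control statistics, mean + 1 SD ("above") or
    mean - 1 SD ("below") marks values unusual relative to the control
    condition (e.g. boundary formation above serum-free controls).
    """
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < 2:
        raise InvalidArgumentError("need at least 2 control values")
    if side not in ("above", "below"):
        raise InvalidArgumentError("side must be 'above' or 'below'")
    sd = vals.std(ddof=1)
    return float(vals.mean() + sd if side == "above" else vals.mean() - sd)
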