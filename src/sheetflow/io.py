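"""Video readers and the HDF5 track-bundle container.

A *track bundle* is the persistent product of the tracking stage: per
channel the (n, T, 2) track array, the superpixel grid, the configuration
that produced it and provenance (package version, seed).  Tracks compress
a multi-gigabyte video into a container of a couple of megabytes that all
downstream statistics can be computed from without re-reading the video.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .exceptions import FormatError, InvalidArgumentError
from .tracking import SuperpixelGrid, TrackArray, VideoStack

__all__ = ["TrackBundle", "load_video", "save_bundle", "load_bundle"]

FORMAT_VERSION = 1


@dataclass
class TrackBundle:
    """Tracks per channel + grid + config snapshot + provenance."""

    tracks: dict[str, TrackArray]
    grid: SuperpixelGrid
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = {tr.n_frames for tr in self.tracks.values()}
        if len(T) > 1:
            raise InvalidArgumentError("channels disagree on frame count")


def load_video(path: str | Path, channels: list[int] | None = None) -> VideoStack:
    """Read a multi-page TIFF or a directory of numbered frame images.

    Frames are returned as (T, H, W, C) with the raw integer dtype.  For a
    directory, files are taken in sorted name order and must share shape.
    ``channels`` selects a channel subset by index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if len(files) < 2:
            raise FormatError(f"need >= 2 frame images in {path}")
        frames = []
        for f in files:
            img = iio.imread(f)
            if frames and img.shape != frames[0].shape:
                raise FormatError(
                    f"frame {f.name} shape {img.shape} != {frames[0].shape}"
                )
            frames.append(img)
        arr = np.stack(frames)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types
            raise FormatError(f"cannot read {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., None]
    elif arr.ndim == 4 and arr.shape[1] <= 4 < arr.shape[-1]:
        arr = np.moveaxis(arr, 1, -1)  # (T, C, H, W) -> (T, H, W, C)
    if arr.ndim != 4:
        raise FormatError(f"unsupported video shape {arr.shape}")
    if channels is not None:
        arr = arr[..., channels]
    return VideoStack(frames=arr)


def save_bundle(bundle: TrackBundle, path: str | Path) -> None:
    """Write a bundle to HDF5 (arrays + JSON attributes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["tool_version"] = __version__
        f.attrs["config"] = json.dumps(bundle.config)
        f.attrs["provenance"] = json.dumps(bundle.provenance)
        g = f.create_group("tracks")
        for name, tr in bundle.tracks.items():
            gg = g.create_group(name)
            gg.create_dataset("positions", data=tr.positions, compression="gzip")
            gg.create_dataset("spawn_frame", data=tr.spawn_frame)
            gg.create_dataset(
                "origin", data=np.asarray(tr.origin, dtype="S")
            )
        gr = f.create_group("grid")
        gr.create_dataset("labels", data=bundle.grid.labels, compression="gzip")
        gr.create_dataset("centroids", data=bundle.grid.centroids)
        gr.attrs["avg_width"] = bundle.grid.avg_width


def load_bundle(path: str | Path) -> TrackBundle:
    """Read a bundle written by :func:`save_bundle`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise FormatError(
                    f"bundle format version {version} != expected {FORMAT_VERSION}"
                )
            tracks = {}
            for name, gg in f["tracks"].items():
                tracks[name] = TrackArray(
                    positions=gg["positions"][()],
                    spawn_frame=gg["spawn_frame"][()],
                    origin=np.asarray(
                        [s.decode() for s in gg["origin"][()]], dtype=object
                    ),
                )
            grid = SuperpixelGrid(
                labels=f["grid/labels"][()],
                centroids=f["grid/centroids"][()],
                avg_width=float(f["grid"].attrs["avg_width"]),
            )
            config = json.loads(f.attrs.get("config", "{}"))
            provenance = json.loads(f.attrs.get("provenance", "{}"))
    except (OSError, KeyError) as exc:
        raise FormatError(f"corrupted or invalid bundle {path}: {exc}") from exc
    return TrackBundle(tracks=tracks, grid=grid, config=config, provenance=provenance)
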