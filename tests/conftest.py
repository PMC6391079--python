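"""Shared fixtures: small grids, rigid-motion tracks, one tracked synthetic video."""

from __future__ import annotations

import numpy as np
import pytest

import sheetflow as sf


def make_rigid_tracks(grid: sf.SuperpixelGrid, drift, n_frames: int) -> sf.TrackArray:
    """Tracks translating the whole grid by ``drift`` px per frame."""
    drift = np.asarray(drift, dtype=float)
    pos = grid.centroids[:, None, :] + drift * np.arange(n_frames)[None, :, None]
    return sf.TrackArray(positions=pos)


@pytest.fixture(scope="session")
def grid20x20() -> sf.SuperpixelGrid:
    return sf.make_superpixel_grid(200, 200, 400)


@pytest.fixture(scope="session")
def sheet_scenario():
    """One rendered + tracked stable-boundary video (shared across tests)."""
    spec = sf.ScenarioSpec(
        scenario="stable_boundary",
        shape=(160, 224),
        gap_width=84,
        speed_left=3.0,
        speed_right=3.0,
        n_frames=42,
        seed=0,
    )
    video, truth = sf.render_two_sheet_video(spec)
    bundle = sf.track_video(
        video,
        n_superpixels=150,
        assign=False,
        seed=0,
        flow_params={"radius": 7, "num_warp": 3},
    )
    return spec, video, truth, bundle
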