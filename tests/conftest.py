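"""Shared fixtures: all synthetic, generated at test time."""

import numpy as np
import pytest

from nirsmoco import simulate
from nirsmoco.containers import RoiSpec


def make_even_trajectory(n_frames: int, seed: int = 3, step_every: int = 10) -> np.ndarray:
    """Piecewise-constant integer trajectory with even-pixel steps.

    Even steps keep the scene aligned on the level-1 decimated grid, matching
    the tracker's +/- 2**level px accuracy contract.
    """
    rng = np.random.default_rng(seed)
    traj = np.zeros((n_frames, 2))
    pos = np.zeros(2)
    for k in range(1, n_frames):
        if k % step_every == 0:
            pos = pos + rng.choice([-4, -2, 0, 2, 4], size=2)
        traj[k] = pos
    return traj


@pytest.fixture(scope="session")
def tracked_video():
    """A 60-frame thermal video with known trajectory and 5 occluded frames,
    plus the ROI over the first detector."""
    n = 60
    occl = (20, 21, 22, 23, 24)
    traj = make_even_trajectory(n)
    video, gt = simulate.synth_thermal_video(
        n_frames=n, trajectory=traj, occlusion_frames=occl, seed=1
    )
    layout = gt.extras["layout"]
    det = gt.extras["face_center0"] + np.asarray(layout["detectors"][0])
    roi = RoiSpec(
        mroi_center=(float(det[0]), float(det[1])),
        mroi_height=80,
        mroi_width=80,
        srois=((10.0, -15.0, 4.0, 4.0), (-12.0, 18.0, 4.0, 4.0)),
    )
    return video, gt, roi, occl


@pytest.fixture(scope="session")
def band_limited_signal():
    """300 s, 10 Hz sum of sinusoids spanning 0.05-1.5 Hz."""
    fs = 10.0
    t = np.arange(3000) / fs
    rng = np.random.default_rng(0)
    x = np.zeros_like(t)
    for f in (0.05, 0.1, 0.25, 0.5, 1.1, 1.5):
        x += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x, fs
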