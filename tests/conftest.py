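import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from endodance.presets import get_preset
from endodance.synthetic import (OpticsConfig, RootHairGeometry,
                                 SimulationGroundTruth)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def geometry():
    return RootHairGeometry.for_stage("growing")


@pytest.fixture
def quiet_optics():
    """Spinning-disc optics with noise disabled, for exact-value checks."""
    return OpticsConfig(noise=False)


def make_truth(geometry, trajectories, frame_interval=0.1, intensity=2.5,
               diameter_nm=250.0, fov=None):
    """Hand-scripted ground truth from per-particle position arrays.

    ``trajectories`` maps particle_id -> (n, 2) array of (x, y) um, all of
    equal length, sampled at ``frame_interval``.
    """
    rows = []
    n_frames = 0
    for pid, xy in trajectories.items():
        xy = np.asarray(xy, dtype=float)
        n_frames = max(n_frames, len(xy))
        inten = intensity[pid] if isinstance(intensity, dict) else intensity
        diam = diameter_nm[pid] if isinstance(diameter_nm, dict) else diameter_nm
        rows.append(pd.DataFrame({
            "particle_id": pid,
            "frame": np.arange(len(xy)),
            "t": np.arange(len(xy)) * frame_interval,
            "x": xy[:, 0], "y": xy[:, 1],
            "intensity": inten, "apparent_diameter_nm": diam,
            "motion_state": "go", "kind": "scripted",
        }))
    particles = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return SimulationGroundTruth(
        particles=particles,
        events=pd.DataFrame(columns=["event_id", "type", "member_ids",
                                     "product_id", "t_start", "t_end"]),
        frame_interval=frame_interval, n_frames=n_frames,
        fov_um=fov or geometry.fov_um(), geometry=geometry,
        preset=get_preset("FYVE"))


def make_tracks(trajectories, frame_interval=0.1, intensities=None,
                frame_offsets=None):
    """Hand-scripted track table (track_id -> (n, 2) positions in um)."""
    rows = []
    for tid, xy in trajectories.items():
        xy = np.asarray(xy, dtype=float)
        off = (frame_offsets or {}).get(tid, 0)
        frames = np.arange(len(xy)) + off
        inten = (intensities or {}).get(tid, 2.5)
        inten = np.broadcast_to(np.asarray(inten, dtype=float), len(xy))
        rows.append(pd.DataFrame({
            "track_id": tid, "frame": frames, "t": frames * frame_interval,
            "x": xy[:, 0], "y": xy[:, 1], "intensity": inten,
            "inferred": False,
        }))
    return pd.concat(rows, ignore_index=True)
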