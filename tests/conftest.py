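"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from laurdanscope.records import Snapshot, Trajectory, TrajectoryMeta, WaterRecord
from laurdanscope.synthetic import SynthParams, generate_trajectory


@pytest.fixture(scope="session")
def small_traj() -> Trajectory:
    """8 lipids/leaflet, 30 frames: cheap input for geometry/membrane tests."""
    params = SynthParams(n_lipids_per_leaflet=8, n_waters=40, n_frames=30,
                         tdm_cone_semiangle=30.0, seed=42)
    return generate_trajectory(params)


@pytest.fixture(scope="session")
def gel_traj() -> Trajectory:
    """64 lipids/leaflet, 60 frames: the order-parameter/APL workhorse."""
    params = SynthParams(n_lipids_per_leaflet=64, n_waters=60, n_frames=60,
                         scd_plateau_target=-0.20, apl_target=52.3, seed=7)
    return generate_trajectory(params)


def _unit_perp(v):
    perp = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(v, [1.0, 0.0, 0.0])
    return perp / np.linalg.norm(perp)


def make_water(o_pos, rng=None, bisector=None, h1_direction=None) -> WaterRecord:
    """Water at ``o_pos``, oriented by its H-midpoint bisector or one O-H bond.

    ``bisector`` fixes the O -> (H1+H2)/2 direction (the solvent-orientation
    statistic's reference); ``h1_direction`` instead aims the first O-H bond,
    as hydrogen-bond fixtures need; with neither, the orientation is random.
    """
    o_pos = np.asarray(o_pos, dtype=float)
    if h1_direction is not None:
        d = np.asarray(h1_direction, dtype=float)
        d = d / np.linalg.norm(d)
        q = _unit_perp(d)
        full = np.radians(104.52)
        h1 = o_pos + 0.0957 * d
        h2 = o_pos + 0.0957 * (np.cos(full) * d + np.sin(full) * q)
        return WaterRecord(o_pos=o_pos, h1_pos=h1, h2_pos=h2)
    if bisector is None:
        v = rng.standard_normal(3)
        bisector = v / np.linalg.norm(v)
    else:
        bisector = np.asarray(bisector, dtype=float)
        bisector = bisector / np.linalg.norm(bisector)
    perp = _unit_perp(bisector)
    half = np.radians(104.52 / 2)
    h1 = o_pos + 0.0957 * (np.cos(half) * bisector + np.sin(half) * perp)
    h2 = o_pos + 0.0957 * (np.cos(half) * bisector - np.sin(half) * perp)
    return WaterRecord(o_pos=o_pos, h1_pos=h1, h2_pos=h2)


def bare_snapshot(box, probe=None, waters=(), lipids=(), time=0.0) -> Snapshot:
    return Snapshot(time=time, box=np.asarray(box, dtype=float),
                    lipids=list(lipids), probe=probe, waters=list(waters))


def bare_trajectory(frames, dt=0.1, temperature=298.0, conformer="I",
                    excitation_time=0.0) -> Trajectory:
    meta = TrajectoryMeta(temperature=temperature, conformer=conformer,
                          dt=dt, excitation_time=excitation_time)
    return Trajectory(meta=meta, frames=list(frames))
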