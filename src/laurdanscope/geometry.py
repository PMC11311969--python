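"""Probe orientation and depth statistics.

Angles are measured against the membrane normal (z) and reported over the
full [0, 180] degree range: a dipole lying just above the membrane plane
(~80 deg) is distinct from one just below it (~100 deg), so no folding
across 90 degrees is applied unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .records import Snapshot, Trajectory, check_unit

Z_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass
class AngularDistribution:
    """Histogram of tilt angles with modal angle and half-width."""

    bin_edges: np.ndarray   # degrees, spanning [0, 180]
    counts: np.ndarray
    mode_angle: float       # degrees, center of the maximal bin
    hwhm: float             # degrees, half-width at half the modal count
    mode_drift: float       # degrees, max windowed-mode deviation (diagnostic)


@dataclass
class DepthProfile:
    """|z - center| histograms per species plus the mean phosphate distance."""

    z_bins: np.ndarray                  # nm bin edges from 0
    density: dict[str, np.ndarray]      # per-species histogram densities
    means: dict[str, float]             # per-species mean |z - center|
    mean_p_distance: float              # nm


def tilt_angle(v, normal=Z_AXIS, fold: bool = False) -> float:
    """Angle in degrees between unit vectors ``v`` and ``normal``.

    Raises if either vector deviates from unit norm by more than 1e-3.
    With ``fold=True`` the result is folded into [0, 90] for comparison with
    symmetric conventions.
    """
    v = check_unit(v, 1e-3, "v")
    normal = check_unit(normal, 1e-3, "normal")
    ang = float(np.degrees(np.arccos(np.clip(np.dot(v, normal), -1.0, 1.0))))
    return min(ang, 180.0 - ang) if fold else ang


def _mode_from_hist(counts: np.ndarray, centers: np.ndarray) -> float:
    # ties broken toward the smaller angle (argmax returns the first max)
    return float(centers[int(np.argmax(counts))])


def _hwhm_from_hist(counts: np.ndarray, centers: np.ndarray,
                    bin_width: float) -> float:
    """Half-width at half the modal count, by linear interpolation."""
    imax = int(np.argmax(counts))
    half = counts[imax] / 2.0
    left = right = None
    for i in range(imax, 0, -1):
        if counts[i - 1] <= half:
            # interpolate between centers[i-1] and centers[i]
            frac = (half - counts[i - 1]) / max(counts[i] - counts[i - 1], 1e-300)
            left = centers[i - 1] + frac * (centers[i] - centers[i - 1])
            break
    for i in range(imax, len(counts) - 1):
        if counts[i + 1] <= half:
            frac = (half - counts[i + 1]) / max(counts[i] - counts[i + 1], 1e-300)
            right = centers[i + 1] - frac * (centers[i + 1] - centers[i])
            break
    mode = centers[imax]
    if left is None and right is None:
        return bin_width / 2.0
    if left is None:
        return right - mode
    if right is None:
        return mode - left
    return (right - left) / 2.0


def angle_distribution(
    traj: Trajectory,
    selector: Literal["tdm", "long_axis"] = "tdm",
    bin_width: float = 5.0,
    normal: np.ndarray = Z_AXIS,
    n_windows: int = 4,
) -> AngularDistribution:
    """Histogram of per-frame tilt angles of the probe axis ``selector``.

    The modal angle is the center of the maximal bin (ties to the smaller
    angle); the HWHM comes from linear interpolation of the histogram at half
    the modal count.  ``mode_drift`` reports the largest deviation of
    windowed modes from the global mode, a convergence diagnostic in the
    spirit of requiring orientational fluctuations below ~5 degrees.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    vecs = traj.tdm_series() if selector == "tdm" else np.array(
        [f.probe.long_axis for f in traj.frames])
    angles = np.degrees(np.arccos(np.clip(vecs @ normal, -1.0, 1.0)))
    # bins centered on multiples of bin_width so a delta at 90 deg reports 90
    edges = np.arange(-bin_width / 2.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = _mode_from_hist(counts, centers)
    hwhm = _hwhm_from_hist(counts.astype(float), centers, bin_width)

    drift = 0.0
    if len(angles) >= n_windows * 2:
        for chunk in np.array_split(angles, n_windows):
            c, _ = np.histogram(chunk, bins=edges)
            drift = max(drift, abs(_mode_from_hist(c, centers) - mode))
    return AngularDistribution(bin_edges=edges, counts=counts,
                               mode_angle=mode, hwhm=hwhm, mode_drift=drift)


def frame_depths(snap: Snapshot) -> dict[str, float | np.ndarray]:
    """Per-frame |z - membrane center| for the tracked species."""
    center = snap.membrane_center_z()
    p = snap.probe
    out: dict[str, float | np.ndarray] = {
        "phosphorus": np.abs(np.array(
            [l.phosphorus_pos[2] for l in snap.lipids]) - center),
    }
    if p is not None:
        out["head"] = abs(p.head_com[2] - center)
        out["carbonyl_o"] = abs(p.carbonyl_o_pos[2] - center)
        out["amino_n"] = abs(p.amino_n_pos[2] - center)
    return out


def depth_profile(traj: Trajectory, bin_width: float = 0.05,
                  z_max: Optional[float] = None) -> DepthProfile:
    """Distance-from-center histograms for probe head, C=O, N and phosphates.

    The membrane center is recomputed per frame as the midpoint of the
    per-leaflet mean phosphorus z, making the profile invariant under rigid
    z-translations of the frames.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    acc: dict[str, list] = {"head": [], "carbonyl_o": [], "amino_n": [],
                            "phosphorus": []}
    for snap in traj.frames:
        d = frame_depths(snap)
        for k, v in d.items():
            acc[k].extend(np.atleast_1d(v))
    if z_max is None:
        z_max = max(max(v) for v in acc.values() if v) + bin_width
    edges = np.arange(0.0, z_max + bin_width, bin_width)
    density = {}
    means = {}
    for k, v in acc.items():
        arr = np.asarray(v, dtype=float)
        if arr.size:
            density[k], _ = np.histogram(arr, bins=edges, density=True)
            means[k] = float(arr.mean())
        else:
            density[k] = np.zeros(len(edges) - 1)
            means[k] = float("nan")
    return DepthProfile(z_bins=edges, density=density, means=means,
                        mean_p_distance=means["phosphorus"])
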