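"""Membrane phase fingerprints: APL, deuterium order parameters, thickness.

APL is reported in Angstrom^2 (internal lengths are nm, hence the factor
100).  The deuterium order parameter of carbon k is

    S_CD(k) = < (3 cos^2 theta - 1) / 2 >

with theta the angle between the C-H bond and the membrane normal (z),
averaged over hydrogens, lipids and frames.  Thickness maps grid the
lateral plane and difference the per-cell leaflet-mean phosphorus heights;
a rippled bilayer shows up as a striped thickness field whose dominant
wavelength is read off the 2-D spatial power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .records import Snapshot, Trajectory


@dataclass
class OrderParameterProfile:
    tail: Literal["sn1", "sn2", "probe_tail"]
    s_cd: np.ndarray  # per-carbon, glycerol to terminal methyl


@dataclass
class ThicknessMap:
    cell_size: float            # nm (nominal; actual cells evenly divide the box)
    x_edges: np.ndarray
    y_edges: np.ndarray
    grid: np.ndarray            # (nx, ny) thickness in nm
    fill_mask: np.ndarray       # True where the value was interpolated


@dataclass
class PhaseCall:
    label: Literal["Lc", "Lbeta", "Pbeta", "Lalpha"]
    apl: float                  # Angstrom^2
    scd_plateau: float          # mean |S_CD| over plateau carbons
    ripple_rms: float           # nm
    thresholds: dict


@dataclass
class RippleMetrics:
    rms: float                          # nm about the mean thickness
    dominant_wavelength: Optional[float]  # nm, None when flagged flat
    flagged: bool


def area_per_lipid(traj: Trajectory, count_probe: bool = False,
                   allow_unequal: bool = False) -> tuple[np.ndarray, float]:
    """Per-frame and mean area per lipid in Angstrom^2.

    APL = lateral box area / lipids per leaflet; the probe is not counted
    as a lipid unless ``count_probe`` is set (it then adds one molecule to
    its leaflet's count, and the per-leaflet mean is used).
    """
    series = []
    for i, snap in enumerate(traj.frames):
        n_up = len(snap.leaflet_lipids("upper"))
        n_lo = len(snap.leaflet_lipids("lower"))
        if n_up != n_lo and not allow_unequal:
            raise ValueError(
                f"frame {i}: unequal leaflets ({n_up} vs {n_lo}); "
                "pass allow_unequal=True to override")
        counts = [n_up, n_lo]
        if count_probe and snap.probe is not None:
            # assign the probe to the leaflet its head resides in
            zc = snap.membrane_center_z()
            idx = 0 if snap.probe.head_com[2] >= zc else 1
            counts[idx] += 1
        n_per_leaflet = 0.5 * (counts[0] + counts[1])
        area_a2 = float(snap.box[0] * snap.box[1]) * 100.0
        series.append(area_a2 / n_per_leaflet)
    series = np.asarray(series)
    return series, float(series.mean())


def deuterium_order_parameters(
    traj: Trajectory, tail: Literal["sn1", "sn2", "probe_tail"] = "sn1"
) -> OrderParameterProfile:
    """Per-carbon S_CD profile averaged over hydrogens, lipids and frames."""
    num = None
    cnt = None
    for snap in traj.frames:
        if tail == "probe_tail":
            if snap.probe is None or snap.probe.tail_ch.size == 0:
                raise ValueError("probe tail C-H vectors absent")
            chs = [snap.probe.tail_ch]
        else:
            attr = "sn1_ch" if tail == "sn1" else "sn2_ch"
            chs = [getattr(l, attr) for l in snap.lipids]
            if not chs or chs[0].size == 0:
                raise ValueError(f"tail {tail!r} C-H vectors absent")
        for ch in chs:
            cos2 = ch[..., 2] ** 2           # z-component of unit vectors
            s = 0.5 * (3.0 * cos2 - 1.0)     # (n_carbons, n_h)
            per_c = s.sum(axis=-1)
            if num is None:
                num = np.zeros(ch.shape[0])
                cnt = np.zeros(ch.shape[0])
            num += per_c
            cnt += ch.shape[1]
    return OrderParameterProfile(tail=tail, s_cd=num / cnt)


def plateau_scd(profile: OrderParameterProfile,
                carbons: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10)) -> float:
    """Mean S_CD over the plateau carbons (1-based indices)."""
    idx = [c - 1 for c in carbons if c - 1 < len(profile.s_cd)]
    return float(np.mean(profile.s_cd[idx]))


def thickness_map(snap: Snapshot, cell_size: float) -> ThicknessMap:
    """Per-cell leaflet separation (upper-mean z minus lower-mean z).

    Cells with an empty leaflet are filled by nearest-neighbour
    interpolation and flagged in ``fill_mask``.
    """
    lx, ly = float(snap.box[0]), float(snap.box[1])
    if cell_size > min(lx, ly):
        raise ValueError("cell_size larger than the lateral box")
    nx = max(1, int(round(lx / cell_size)))
    ny = max(1, int(round(ly / cell_size)))
    x_edges = np.linspace(0.0, lx, nx + 1)
    y_edges = np.linspace(0.0, ly, ny + 1)
    sums = {"upper": np.zeros((nx, ny)), "lower": np.zeros((nx, ny))}
    nums = {"upper": np.zeros((nx, ny)), "lower": np.zeros((nx, ny))}
    for lip in snap.lipids:
        x, y, z = lip.phosphorus_pos
        i = min(int((x % lx) / lx * nx), nx - 1)
        j = min(int((y % ly) / ly * ny), ny - 1)
        sums[lip.leaflet][i, j] += z
        nums[lip.leaflet][i, j] += 1
    ok = (nums["upper"] > 0) & (nums["lower"] > 0)
    grid = np.full((nx, ny), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = sums["upper"] / nums["upper"]
        lo = sums["lower"] / nums["lower"]
    grid[ok] = (up - lo)[ok]
    fill_mask = ~ok
    if fill_mask.any() and ok.any():
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        good = np.argwhere(ok)
        for (i, j) in np.argwhere(fill_mask):
            # periodic nearest neighbour in cell index space
            di = np.minimum(np.abs(good[:, 0] - i), nx - np.abs(good[:, 0] - i))
            dj = np.minimum(np.abs(good[:, 1] - j), ny - np.abs(good[:, 1] - j))
            k = int(np.argmin(di ** 2 + dj ** 2))
            grid[i, j] = grid[good[k, 0], good[k, 1]]
    return ThicknessMap(cell_size=cell_size, x_edges=x_edges, y_edges=y_edges,
                        grid=grid, fill_mask=fill_mask)


def ripple_metrics(tmap: ThicknessMap) -> RippleMetrics:
    """RMS thickness modulation and dominant lateral wavelength.

    The wavelength comes from the maximum of the 2-D spatial power spectrum
    excluding the zero mode; a flat (or all-interpolated) map is flagged.
    """
    grid = tmap.grid
    nx, ny = grid.shape
    if nx < 4 or ny < 4:
        raise ValueError("thickness map must cover at least 4x4 cells")
    if tmap.fill_mask.all():
        return RippleMetrics(rms=float("nan"), dominant_wavelength=None,
                             flagged=True)
    dev = grid - grid.mean()
    rms = float(np.sqrt(np.mean(dev ** 2)))
    if rms < 1e-9:
        return RippleMetrics(rms=rms, dominant_wavelength=None, flagged=True)
    power = np.abs(np.fft.fft2(dev)) ** 2
    lx = tmap.x_edges[-1] - tmap.x_edges[0]
    ly = tmap.y_edges[-1] - tmap.y_edges[0]
    fx = np.fft.fftfreq(nx, d=lx / nx)
    fy = np.fft.fftfreq(ny, d=ly / ny)
    kx, ky = np.meshgrid(fx, fy, indexing="ij")
    kmag = np.sqrt(kx ** 2 + ky ** 2)
    power[0, 0] = 0.0
    imax = np.unravel_index(int(np.argmax(power)), power.shape)
    k = kmag[imax]
    return RippleMetrics(rms=rms, dominant_wavelength=float(1.0 / k),
                         flagged=False)


DEFAULT_THRESHOLDS = {
    "apl_alpha": 55.0,    # Angstrom^2: at/above -> liquid disordered
    "apl_c": 51.5,        # Angstrom^2: at/below -> liquid crystal
    "order_high": 0.15,   # |S_CD| plateau considered "ordered"
    "ripple_rms": 0.15,   # nm of thickness RMS that marks the ripple phase
}


def classify_phase(apl: float, scd_plateau: float, ripple_rms: float,
                   thresholds: Optional[dict] = None) -> PhaseCall:
    """Heuristic phase label from (APL, plateau order, ripple RMS).

    Rule table: large APL with low order -> Lalpha; small APL with high
    order -> Lc; otherwise gel, promoted to Pbeta when the thickness field
    ripples above threshold.  Labels are advisory fingerprints, mirroring
    how the same features are read off by inspection.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    order = abs(scd_plateau)
    if apl >= th["apl_alpha"] and order < th["order_high"]:
        label = "Lalpha"
    elif apl <= th["apl_c"] and order >= th["order_high"]:
        label = "Lc"
    elif ripple_rms >= th["ripple_rms"]:
        label = "Pbeta"
    else:
        label = "Lbeta"
    return PhaseCall(label=label, apl=apl, scd_plateau=scd_plateau,
                     ripple_rms=ripple_rms, thresholds=th)
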