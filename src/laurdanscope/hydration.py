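"""Water structure and post-excitation relaxation around the probe head.

The central observable is the cumulative solvent orientation: for every
water whose oxygen lies within ``radius`` of the probe head COM, the cosine
of the angle between (head -> O) and (O -> H-midpoint) is summed with an
overall sign of -1, so that an oxygen pointing toward the probe (the
equilibrated, excited-dipole-stabilizing arrangement) contributes
negatively.  Magnitudes therefore scale with the shell population rather
than being normalized means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

from .records import Curve, Snapshot, Trajectory


@dataclass
class RDFResult:
    """Radial distribution of water oxygens about the probe head."""

    r_bins: np.ndarray      # nm, bin centers
    g: np.ndarray           # dimensionless
    coordination: np.ndarray  # cumulative mean count N(r) at the outer edge


@dataclass
class SolventOrientationSeries:
    """Cumulative orientation per post-excitation time window."""

    windows: list[tuple[float, float]]  # ns, relative to excitation
    radius: float                       # nm
    values: np.ndarray                  # signed sums per window
    per_frame_t: np.ndarray             # ns after excitation, every frame
    per_frame_values: np.ndarray


@dataclass
class RelaxationFit:
    """C(t) = A exp(-t/tau) + C_inf fit of the orientation statistic."""

    relax_time: float
    asymptote: float
    amplitude: float
    relax_time_stderr: Optional[float]
    asymptote_stderr: Optional[float]
    converged: bool
    message: str = ""


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


# Table-1-style default windows (ns after excitation)
DEFAULT_WINDOWS = [(0.0, 1.0), (3.0, 4.0), (6.0, 7.0), (9.0, 10.0),
                   (12.0, 13.0), (20.0, 21.0)]


def water_rdf(traj: Trajectory, r_max: float, dr: float,
              density: Optional[float] = None) -> RDFResult:
    """g(r) and coordination number N(r) of water O about the head COM.

    Distances use the minimum-image convention in all three dimensions.
    ``density`` is the reference (ideal-gas) water number density in nm^-3;
    when omitted it defaults to N_waters / V_box, appropriate for waters
    filling the whole box.  For membrane systems pass the solvent-slab
    density explicitly.
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    smallest = min(float(np.min(f.box)) for f in traj.frames)
    if r_max > smallest / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box edge")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    dens_acc = 0.0
    for snap in traj.frames:
        if snap.probe is None or not snap.waters:
            raise ValueError("RDF requires probe and waters in every frame")
        d = _min_image(snap.water_o - snap.probe.head_com, snap.box)
        r = np.linalg.norm(d, axis=1)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        dens_acc += len(snap.waters) / float(np.prod(snap.box))
    n_frames = len(traj.frames)
    counts /= n_frames
    rho = density if density is not None else dens_acc / n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (rho * shell_vol)
    return RDFResult(r_bins=0.5 * (edges[:-1] + edges[1:]), g=g,
                     coordination=np.cumsum(counts))


def shell_occupancy(rdf: RDFResult, shell_r: float,
                    reference_total: int) -> float:
    """Percent of ``reference_total`` waters found within ``shell_r``."""
    if reference_total == 0:
        raise ValueError("reference_total must be nonzero")
    edges_r = rdf.r_bins + 0.5 * (rdf.r_bins[1] - rdf.r_bins[0])
    if shell_r > edges_r[-1] + 1e-9:
        raise ValueError("shell_r outside the RDF range")
    idx = np.searchsorted(edges_r, shell_r - 1e-12)
    n = rdf.coordination[min(idx, len(rdf.coordination) - 1)] \
        if shell_r >= edges_r[0] else 0.0
    return 100.0 * float(n) / reference_total


def count_hbonds(snap: Snapshot, region_r: float = 0.5, d_max: float = 0.35,
                 angle_max: float = 30.0) -> int:
    """Water-donor -> probe-acceptor hydrogen bonds near the head group.

    Geometric criterion: donor(O_w)-acceptor distance <= ``d_max`` and
    H-O_w-acceptor angle <= ``angle_max``; only waters whose O lies within
    ``region_r`` of the head COM are considered.  Acceptors are the probe's
    carbonyl oxygen and amino nitrogen.
    """
    if snap.probe is None:
        raise ValueError("snapshot has no probe")
    head = snap.probe.head_com
    acceptors = [snap.probe.carbonyl_o_pos, snap.probe.amino_n_pos]
    box = snap.box
    count = 0
    for w in snap.waters:
        if np.linalg.norm(_min_image(w.o_pos - head, box)) > region_r:
            continue
        for acc in acceptors:
            da = _min_image(acc - w.o_pos, box)
            dist = np.linalg.norm(da)
            if dist > d_max or dist == 0:
                continue
            for h in (w.h1_pos, w.h2_pos):
                oh = _min_image(h - w.o_pos, box)
                cosang = np.dot(oh, da) / (np.linalg.norm(oh) * dist)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang <= angle_max:
                    count += 1  # one bond per (water, acceptor) pair
                    break
    return count


def frame_orientation_statistic(snap: Snapshot, radius: float,
                                sign: float = -1.0) -> float:
    """sign * sum of cos(theta) over in-radius waters (see module docstring)."""
    if snap.probe is None:
        raise ValueError("snapshot has no probe")
    head = snap.probe.head_com
    total = 0.0
    for w in snap.waters:
        v1 = _min_image(w.o_pos - head, snap.box)
        r = np.linalg.norm(v1)
        if r > radius or r == 0:
            continue
        mid = 0.5 * (w.h1_pos + w.h2_pos)
        v2 = mid - w.o_pos
        n2 = np.linalg.norm(v2)
        if n2 == 0:
            continue
        total += float(np.dot(v1, v2) / (r * n2))
    return sign * total


def cumulative_solvent_orientation(
    traj: Trajectory,
    radius: float = 1.0,
    windows: Sequence[tuple[float, float]] = tuple(DEFAULT_WINDOWS),
    sign: float = -1.0,
) -> SolventOrientationSeries:
    """Windowed cumulative solvent orientation after excitation.

    Windows are (start, end) in ns relative to the excitation time; the
    window value is the mean of the per-frame statistic over frames whose
    post-excitation time falls in [start, end).
    """
    t_exc = traj.meta.excitation_time
    for (a, b) in windows:
        if a < 0 or b <= a:
            raise ValueError(f"invalid window ({a}, {b}): must be after excitation")
    rel_t, vals = [], []
    for snap in traj.frames:
        trel = snap.time - t_exc
        if trel < -1e-12:
            continue
        rel_t.append(trel)
        vals.append(frame_orientation_statistic(snap, radius, sign))
    rel_t = np.asarray(rel_t)
    vals = np.asarray(vals)
    wvals = []
    for (a, b) in windows:
        mask = (rel_t >= a) & (rel_t < b)
        wvals.append(float(vals[mask].mean()) if mask.any() else float("nan"))
    return SolventOrientationSeries(
        windows=[tuple(w) for w in windows], radius=radius,
        values=np.asarray(wvals), per_frame_t=rel_t, per_frame_values=vals)


def _relax_model(t, amplitude, tau, c_inf):
    return amplitude * np.exp(-t / tau) + c_inf


def fit_solvent_relaxation(series: SolventOrientationSeries | tuple
                           ) -> RelaxationFit:
    """Fit C(t) = A exp(-t/tau) + C_inf to the per-frame statistic.

    Accepts a SolventOrientationSeries or a bare (t, values) pair.  A
    degenerate (constant or non-convergent) fit is returned flagged rather
    than raised.
    """
    if isinstance(series, SolventOrientationSeries):
        t, y = series.per_frame_t, series.per_frame_values
    else:
        t, y = np.asarray(series[0], float), np.asarray(series[1], float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points to fit relaxation")
    span = float(np.ptp(y))
    if span < 1e-12:
        return RelaxationFit(float("nan"), float(np.mean(y)), 0.0, None, None,
                             converged=False, message="constant series")
    model = Model(_relax_model)
    t_scale = max(float(np.ptp(t)) / 3.0, 1e-6)
    params = model.make_params(
        amplitude=y[0] - y[-1], tau=t_scale, c_inf=y[-1])
    params["tau"].min = 1e-6
    try:
        res = model.fit(y, params, t=t)
    except Exception as exc:  # pragma: no cover - lmfit rarely raises here
        return RelaxationFit(float("nan"), float("nan"), float("nan"),
                             None, None, False, f"fit error: {exc}")
    tau = float(res.params["tau"].value)
    ok = bool(res.success) and tau < 100.0 * float(np.ptp(t))
    return RelaxationFit(
        relax_time=tau,
        asymptote=float(res.params["c_inf"].value),
        amplitude=float(res.params["amplitude"].value),
        relax_time_stderr=(None if res.params["tau"].stderr is None
                           else float(res.params["tau"].stderr)),
        asymptote_stderr=(None if res.params["c_inf"].stderr is None
                          else float(res.params["c_inf"].stderr)),
        converged=ok,
        message="" if ok else "fit did not converge cleanly",
    )
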