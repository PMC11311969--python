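"""Synthetic bilayer/probe/water trajectories and emission tables.

The generator fabricates the statistical structure the analysis stages
assume, with every target quantity known exactly:

* lipids on a jittered lattice whose lateral box area is exactly
  ``n_lipids_per_leaflet * apl_target``;
* leaflet phosphorus sheets at ``+-half_thickness`` modulated by a sinusoidal
  ripple of given amplitude and wavelength (leaflets displaced in opposite z
  directions, so the thickness field carries the ripple at twice the
  single-leaflet amplitude);
* chain C-H unit vectors drawn so the expected deuterium order parameter of
  plateau carbons equals ``scd_plateau_target``;
* a probe transition dipole performing discrete-step rotational diffusion
  confined to a cone (wobbling-in-cone), whose long-time anisotropy plateau
  has the closed form ``r_inf/r0 = [cos(tc) (1 + cos(tc)) / 2]^2``;
* waters uniformly filling the solvent slabs whose orientation statistic
  relaxes exponentially toward ``equilibrated_orientation_mean`` after the
  excitation time;
* emission wavelengths Gaussian about a temperature-dependent mean.

Randomness is split into per-component streams from the master seed, so
enabling or resizing one component never shifts another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import (
    Curve,
    EmissionRecord,
    LipidRecord,
    ProbeRecord,
    Snapshot,
    Trajectory,
    TrajectoryMeta,
    WaterRecord,
)

OH_BOND = 0.0957  # nm, TIP3P-like O-H bond length
HOH_ANGLE = 104.52  # degrees
WATER_SLAB = 1.8  # nm of solvent on each side of the membrane

# carbons (1-based) treated as the order-parameter plateau region
PLATEAU_CARBONS = (3, 4, 5, 6, 7, 8, 9, 10)


@dataclass
class SynthParams:
    """Ground-truth parameters of the synthetic study conditions.

    Defaults emulate a DPPC bilayer in the gel region with an embedded
    Laurdan probe: 64 lipids per leaflet, APL ~52.3 A^2, plateau |S_CD| ~0.2,
    half-thickness 2.1 nm, and a dipole wobbling in a 30 degree cone.
    """

    n_lipids_per_leaflet: int = 64
    apl_target: float = 52.3        # Angstrom^2
    scd_plateau_target: float = -0.20
    half_thickness: float = 2.1     # nm
    ripple_amplitude: float = 0.0   # nm (single-leaflet)
    ripple_wavelength: float = 2.5  # nm
    n_waters: int = 500
    conformer: str = "I"
    probe_depth: float = 1.8        # nm of head COM from center, near the interface
    tdm_cone_semiangle: float = 30.0   # degrees
    tdm_wobble_rate: float = 0.5    # ns^-1, rotational diffusion coefficient
    water_relax_time: float = 2.0   # ns
    equilibrated_orientation_mean: float = 0.4  # per-water asymptote in [-1, 1]
    emission_mean: float = 430.0    # nm
    emission_sigma: float = 10.0    # nm
    n_frames: int = 100
    dt: float = 0.1                 # ns
    excitation_time: float = 0.0    # ns
    seed: int = 0
    # secondary knobs (not part of the core ground truth)
    n_chain_carbons: int = 15
    n_probe_tail_carbons: int = 11
    temperature: float = 298.0
    f_band: tuple[float, float] = (0.2, 0.6)
    conf2_redshift: float = 15.0    # nm, Conf-II emission offset in mixed tables
    p_noise: float = 0.02           # nm, phosphorus positional jitter
    orientation_noise: float = 0.25  # std of per-water cos(theta) about its mean

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0 or self.n_waters < 0 or self.n_frames <= 0:
            raise ValueError("counts must be positive")
        if self.apl_target < 40.0:
            raise ValueError(
                f"apl_target {self.apl_target} A^2 < 40 A^2: lipids would overlap")
        if not (0.0 <= self.tdm_cone_semiangle <= 90.0):
            raise ValueError("tdm_cone_semiangle must be in [0, 90] degrees")
        if self.emission_sigma < 0:
            raise ValueError("emission_sigma must be >= 0")
        if not (-0.5 <= self.scd_plateau_target <= 0.0):
            raise ValueError("scd_plateau_target must be in [-0.5, 0]")
        if not (-1.0 <= self.equilibrated_orientation_mean <= 1.0):
            raise ValueError("equilibrated_orientation_mean must be in [-1, 1]")


# ------------------------------------------------------------------ dipoles


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def sample_uniform_cap(rng: np.random.Generator, axis: np.ndarray,
                       semiangle_deg: float) -> np.ndarray:
    """Uniform (solid-angle) draw from the spherical cap about ``axis``."""
    cos_c = math.cos(math.radians(semiangle_deg))
    cos_t = rng.uniform(cos_c, 1.0)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    e1, e2 = _perp_basis(axis)
    return cos_t * axis + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)


def simulate_dipole_wobble(
    n_frames: int,
    dt: float,
    d_rot: float,
    cone_semiangle: Optional[float],
    rng: np.random.Generator,
    axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> np.ndarray:
    """Discrete-step rotational diffusion of a unit vector.

    Each step composes a small random rotation with tangent-plane Gaussian
    components of variance ``2 * d_rot * dt`` each (so the mean squared
    angular step is ``4 * d_rot * dt``).  With ``cone_semiangle`` set, steps
    leaving the cone about ``axis`` are rejected (Metropolis with a symmetric
    proposal), whose stationary law is uniform on the spherical cap.  With
    ``cone_semiangle=None`` the walk is free isotropic rotational diffusion,
    for which the dipole autocorrelation obeys
    ``<P2(u(0).u(t))> = exp(-6 d_rot t)``.

    Returns an ``(n_frames, 3)`` array of unit vectors.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_c = None if cone_semiangle is None else math.cos(math.radians(cone_semiangle))
    if cone_semiangle is not None:
        u = sample_uniform_cap(rng, axis, cone_semiangle)
    else:
        v = rng.standard_normal(3)
        u = v / np.linalg.norm(v)
    out = np.empty((n_frames, 3))
    step_sigma = math.sqrt(2.0 * d_rot * dt)
    if cone_semiangle == 0.0 or d_rot == 0.0:
        out[:] = u if cone_semiangle != 0.0 else axis
        return out
    for i in range(n_frames):
        out[i] = u
        gx, gy = rng.standard_normal(2) * step_sigma
        ang = math.hypot(gx, gy)
        if ang > 0:
            e1, e2 = _perp_basis(u)
            rot_axis = (gx * e1 + gy * e2) / ang
            cand = _rotate_about(u, rot_axis, ang)
            cand /= np.linalg.norm(cand)
            if cos_c is None or np.dot(cand, axis) >= cos_c:
                u = cand
    return out


# ------------------------------------------------------------------ chains


def _sample_ch_vectors(rng: np.random.Generator, scd: np.ndarray,
                       size: tuple[int, ...]) -> np.ndarray:
    """Draw C-H unit vectors with E[(3 cos^2 t - 1)/2] = scd per carbon.

    cos^2(theta) is Beta-distributed with mean (2 S + 1) / 3 (exact in
    expectation); the sign of cos(theta) and the azimuth are uniform.
    ``scd`` must broadcast against ``size``; returns ``size + (3,)``.
    """
    m = (2.0 * np.asarray(scd) + 1.0) / 3.0
    m = np.clip(np.broadcast_to(m, size), 1e-4, 1 - 1e-4)
    kappa = 30.0
    u = rng.beta(m * kappa, (1.0 - m) * kappa)
    cos_t = np.sqrt(u) * rng.choice([-1.0, 1.0], size=size)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=size)
    return np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)


def _chain_scd_profile(target: float, n_carbons: int) -> np.ndarray:
    """Per-carbon expected S_CD: flat plateau, disorder growing tailward."""
    prof = np.full(n_carbons, target)
    last_plateau = PLATEAU_CARBONS[-1]
    for k in range(last_plateau, n_carbons):
        frac = (k - last_plateau + 1) / max(1, n_carbons - last_plateau)
        prof[k] = target * (1.0 - 0.7 * frac)
    return prof


# ------------------------------------------------------------------ waters


def _water_records(rng: np.random.Generator, o_pos: np.ndarray,
                   head: np.ndarray, mean_stat: float,
                   noise: float) -> list[WaterRecord]:
    """Build waters at given O positions with E[-cos(theta)] = mean_stat.

    theta is the angle between head->O and O->(H midpoint); the analysis
    statistic carries sign -1, so the water bisector is drawn with
    E[cos(theta)] = -mean_stat.
    """
    n = len(o_pos)
    c = np.clip(-mean_stat + noise * rng.standard_normal(n), -0.999, 0.999)
    half = math.radians(HOH_ANGLE / 2.0)
    records = []
    for i in range(n):
        v1 = o_pos[i] - head
        v1 /= np.linalg.norm(v1)
        e1, e2 = _perp_basis(v1)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        s = math.sqrt(max(0.0, 1.0 - c[i] ** 2))
        bis = c[i] * v1 + s * (math.cos(phi) * e1 + math.sin(phi) * e2)
        # hydrogens at +-(HOH/2) from the bisector, in a random plane
        perp = np.cross(bis, _perp_basis(bis)[0])
        perp /= np.linalg.norm(perp)
        h1 = o_pos[i] + OH_BOND * (math.cos(half) * bis + math.sin(half) * perp)
        h2 = o_pos[i] + OH_BOND * (math.cos(half) * bis - math.sin(half) * perp)
        records.append(WaterRecord(o_pos=o_pos[i], h1_pos=h1, h2_pos=h2))
    return records


# ------------------------------------------------------------------ driver


def _lattice_dims(n: int) -> tuple[int, int]:
    ny = int(math.sqrt(n))
    while n % ny:
        ny -= 1
    return n // ny, ny


def generate_trajectory(params: SynthParams) -> Trajectory:
    """Generate a bilayer+probe+water trajectory from the ground truth."""
    p = params
    master = np.random.SeedSequence(p.seed)
    ss_lip, ss_probe, ss_wat, _ = master.spawn(4)
    rng_lip = np.random.default_rng(ss_lip)
    rng_probe = np.random.default_rng(ss_probe)
    rng_wat = np.random.default_rng(ss_wat)

    n = p.n_lipids_per_leaflet
    apl_nm2 = p.apl_target / 100.0
    nx, ny = _lattice_dims(n)
    a = math.sqrt(apl_nm2)
    lx, ly = nx * a, ny * a  # lateral area = n * apl_nm2 exactly
    z_extent = p.half_thickness + p.ripple_amplitude
    lz = 2.0 * (z_extent + WATER_SLAB)
    zc = lz / 2.0
    box = np.array([lx, ly, lz])

    # lattice sites shared by both leaflets
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    site_x = (gx.ravel() + 0.5) * a
    site_y = (gy.ravel() + 0.5) * a

    scd_prof = _chain_scd_profile(p.scd_plateau_target, p.n_chain_carbons)
    probe_scd = _chain_scd_profile(p.scd_plateau_target, p.n_probe_tail_carbons)

    # fixed water O positions in the two solvent slabs
    n_up = p.n_waters // 2
    slab_lo_top = zc - z_extent - 0.2
    slab_up_bot = zc + z_extent + 0.2
    o_up = np.column_stack([
        rng_wat.uniform(0, lx, n_up),
        rng_wat.uniform(0, ly, n_up),
        rng_wat.uniform(slab_up_bot, lz - 0.05, n_up),
    ])
    o_lo = np.column_stack([
        rng_wat.uniform(0, lx, p.n_waters - n_up),
        rng_wat.uniform(0, ly, p.n_waters - n_up),
        rng_wat.uniform(0.05, slab_lo_top, p.n_waters - n_up),
    ])
    o_all = np.vstack([o_up, o_lo])

    # probe dipole paths over the whole run
    tdm_path = simulate_dipole_wobble(
        p.n_frames, p.dt, p.tdm_wobble_rate, p.tdm_cone_semiangle, rng_probe)
    ax_tilt = math.radians(40.0)
    long_axis_ref = np.array([math.sin(ax_tilt), 0.0, math.cos(ax_tilt)])
    axis_path = simulate_dipole_wobble(
        p.n_frames, p.dt, p.tdm_wobble_rate, p.tdm_cone_semiangle,
        rng_probe, axis=long_axis_ref)

    head = np.array([lx / 2.0, ly / 2.0, zc + p.probe_depth])
    amino_off = 0.15 if p.conformer == "II" else -0.15
    frames: list[Snapshot] = []
    for fi in range(p.n_frames):
        t = fi * p.dt
        lipids: list[LipidRecord] = []
        for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
            px = site_x + rng_lip.uniform(-0.2 * a, 0.2 * a, n)
            py = site_y + rng_lip.uniform(-0.2 * a, 0.2 * a, n)
            ripple = p.ripple_amplitude * np.sin(2.0 * np.pi * px
                                                 / p.ripple_wavelength)
            pz = zc + sign * (p.half_thickness + ripple) \
                + p.p_noise * rng_lip.standard_normal(n)
            ch = _sample_ch_vectors(
                rng_lip, scd_prof[:, None], (n, 2, p.n_chain_carbons, 2))
            # carbon positions descend from the phosphate toward the center
            ks = np.arange(1, p.n_chain_carbons + 1)
            cz = pz[:, None] - sign * 0.125 * ks[None, :]
            for i in range(n):
                cxy = np.column_stack([
                    np.full(p.n_chain_carbons, px[i]),
                    np.full(p.n_chain_carbons, py[i])])
                sn1_c = np.column_stack([cxy, cz[i]])
                sn2_c = sn1_c + np.array([0.05, 0.05, 0.0])
                lipids.append(LipidRecord(
                    phosphorus_pos=np.array([px[i], py[i], pz[i]]),
                    leaflet=leaflet,
                    sn1_carbons=sn1_c,
                    sn1_ch=ch[i, 0],
                    sn2_carbons=sn2_c,
                    sn2_ch=ch[i, 1],
                ))
        tail_ks = np.arange(1, p.n_probe_tail_carbons + 1)
        tail_c = head[None, :] - np.column_stack([
            np.zeros_like(tail_ks, dtype=float),
            np.zeros_like(tail_ks, dtype=float),
            0.125 * tail_ks.astype(float)])
        tail_ch = _sample_ch_vectors(
            rng_probe, probe_scd[:, None], (p.n_probe_tail_carbons, 2))
        probe = ProbeRecord(
            head_com=head.copy(),
            tdm=tdm_path[fi],
            long_axis=axis_path[fi],
            carbonyl_o_pos=head + np.array([0.0, 0.0, -0.12]),
            amino_n_pos=head + np.array([0.0, 0.0, amino_off]),
            tail_carbons=tail_c,
            tail_ch=tail_ch,
        )
        if t < p.excitation_time:
            mean_stat = 0.0
        else:
            mean_stat = p.equilibrated_orientation_mean * (
                1.0 - math.exp(-(t - p.excitation_time) / p.water_relax_time))
        waters = _water_records(rng_wat, o_all, head, mean_stat,
                                p.orientation_noise)
        frames.append(Snapshot(time=t, box=box.copy(), lipids=lipids,
                               probe=probe, waters=waters))

    meta = TrajectoryMeta(temperature=p.temperature, conformer=p.conformer,
                          dt=p.dt, excitation_time=p.excitation_time)
    return Trajectory(meta=meta, frames=frames)


def generate_emission_table(params: SynthParams, n_records: int
                            ) -> list[EmissionRecord]:
    """Draw per-snapshot emission wavelengths and oscillator strengths.

    Wavelengths are Normal(emission_mean, emission_sigma) truncated to
    > 200 nm; oscillator strengths uniform in ``params.f_band``.  For the
    ``mixed`` conformer, records alternate Conf-I / Conf-II with the
    Conf-II mean red-shifted by ``conf2_redshift``.
    """
    if n_records <= 0:
        raise ValueError("n_records must be > 0")
    p = params
    master = np.random.SeedSequence(p.seed)
    rng = np.random.default_rng(master.spawn(4)[3])
    records = []
    for i in range(n_records):
        if p.conformer == "mixed":
            conf = "I" if i % 2 == 0 else "II"
        else:
            conf = p.conformer
        mean = p.emission_mean + (p.conf2_redshift if conf == "II" else 0.0)
        lam = mean if p.emission_sigma == 0 else \
            float(rng.normal(mean, p.emission_sigma))
        while lam <= 200.0:
            lam = float(rng.normal(mean, p.emission_sigma))
        f = float(rng.uniform(*p.f_band))
        records.append(EmissionRecord.from_wavelength(i, conf, lam, f))
    return records


def wobble_plateau_ratio(cone_semiangle_deg: float) -> float:
    """Closed-form wobbling-in-cone plateau: r_inf/r0 = [c(1+c)/2]^2."""
    c = math.cos(math.radians(cone_semiangle_deg))
    return (c * (1.0 + c) / 2.0) ** 2
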