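"""Core data containers for bilayer/probe/water trajectories and optical records.

All lengths are in nm, times in ns, temperatures in K. The z axis is the
membrane normal; the membrane center is the midpoint between the per-leaflet
mean phosphorus z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

# Planck relation in (eV . nm): E[eV] = EV_NM / lambda[nm]
EV_NM = 1239.84193

Conformer = Literal["I", "II", "mixed"]
Leaflet = Literal["upper", "lower"]

_UNIT_TOL = 1e-6


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def check_unit(v: np.ndarray, tol: float = 1e-3, name: str = "vector") -> np.ndarray:
    v = _as_vec3(v)
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise ValueError(f"{name} is not unit-norm (|v| = {n:.6f})")
    return v / n


@dataclass
class TrajectoryMeta:
    """Per-run metadata carried in the sidecar file.

    temperature : K of the production run.
    conformer : which Laurdan conformer is embedded ("I", "II" or "mixed").
    dt : frame spacing in ns.
    excitation_time : ns at which the probe is switched to its S1 charge set;
        solvent-relaxation windows are measured relative to this instant.
    """

    temperature: float
    conformer: Conformer
    dt: float
    excitation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.dt <= 0:
            raise ValueError("dt must be > 0 ns")
        if self.excitation_time < 0:
            raise ValueError("excitation_time must be >= 0 ns")
        if self.conformer not in ("I", "II", "mixed"):
            raise ValueError(f"unknown conformer {self.conformer!r}")


@dataclass
class LipidRecord:
    """One DPPC lipid: phosphorus position, leaflet, and per-carbon C-H vectors.

    sn1_carbons / sn2_carbons: (n_carbons, 3) carbon positions ordered from
    glycerol to terminal methyl.  sn1_ch / sn2_ch: (n_carbons, n_h, 3) unit
    vectors from each carbon to its attached hydrogens.
    """

    phosphorus_pos: np.ndarray
    leaflet: Leaflet
    sn1_carbons: np.ndarray
    sn1_ch: np.ndarray
    sn2_carbons: np.ndarray
    sn2_ch: np.ndarray

    def __post_init__(self) -> None:
        self.phosphorus_pos = _as_vec3(self.phosphorus_pos)
        if self.leaflet not in ("upper", "lower"):
            raise ValueError(f"unknown leaflet {self.leaflet!r}")
        for attr in ("sn1_carbons", "sn2_carbons", "sn1_ch", "sn2_ch"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))


@dataclass
class ProbeRecord:
    """The Laurdan probe: head-group COM, dipole axes, heteroatom anchors, tail."""

    head_com: np.ndarray
    tdm: np.ndarray
    long_axis: np.ndarray
    carbonyl_o_pos: np.ndarray
    amino_n_pos: np.ndarray
    tail_carbons: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    tail_ch: np.ndarray = field(default_factory=lambda: np.zeros((0, 2, 3)))

    def __post_init__(self) -> None:
        self.head_com = _as_vec3(self.head_com)
        self.tdm = check_unit(self.tdm, _UNIT_TOL * 10, "tdm")
        self.long_axis = check_unit(self.long_axis, _UNIT_TOL * 10, "long_axis")
        self.carbonyl_o_pos = _as_vec3(self.carbonyl_o_pos)
        self.amino_n_pos = _as_vec3(self.amino_n_pos)
        self.tail_carbons = np.asarray(self.tail_carbons, dtype=float)
        self.tail_ch = np.asarray(self.tail_ch, dtype=float)


@dataclass
class WaterRecord:
    """A three-site water (O, H1, H2)."""

    o_pos: np.ndarray
    h1_pos: np.ndarray
    h2_pos: np.ndarray

    def __post_init__(self) -> None:
        self.o_pos = _as_vec3(self.o_pos)
        self.h1_pos = _as_vec3(self.h1_pos)
        self.h2_pos = _as_vec3(self.h2_pos)
        for h in (self.h1_pos, self.h2_pos):
            d = float(np.linalg.norm(h - self.o_pos))
            if not (0.05 < d < 0.15):
                raise ValueError(f"O-H distance {d:.4f} nm outside (0.05, 0.15)")


@dataclass
class Snapshot:
    """One frame: box, lipids, probe, waters."""

    time: float
    box: np.ndarray
    lipids: list[LipidRecord]
    probe: Optional[ProbeRecord]
    waters: list[WaterRecord]

    def __post_init__(self) -> None:
        self.box = _as_vec3(self.box)
        if np.any(self.box <= 0):
            raise ValueError("box dimensions must be positive")

    def leaflet_lipids(self, leaflet: Leaflet) -> list[LipidRecord]:
        return [l for l in self.lipids if l.leaflet == leaflet]

    @property
    def water_o(self) -> np.ndarray:
        """(n_waters, 3) oxygen positions."""
        if not self.waters:
            return np.zeros((0, 3))
        return np.array([w.o_pos for w in self.waters])

    def membrane_center_z(self) -> float:
        """Midpoint between the per-leaflet mean phosphorus z."""
        up = [l.phosphorus_pos[2] for l in self.lipids if l.leaflet == "upper"]
        lo = [l.phosphorus_pos[2] for l in self.lipids if l.leaflet == "lower"]
        if not up or not lo:
            raise ValueError("both leaflets must be populated")
        return 0.5 * (float(np.mean(up)) + float(np.mean(lo)))


@dataclass
class Trajectory:
    """A time-ordered list of snapshots with run metadata."""

    meta: TrajectoryMeta
    frames: list[Snapshot]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def tdm_series(self) -> np.ndarray:
        """(n_frames, 3) transition-dipole unit vectors."""
        out = []
        for f in self.frames:
            if f.probe is None:
                raise ValueError("trajectory has frames without a probe")
            out.append(f.probe.tdm)
        return np.array(out)


@dataclass
class EmissionRecord:
    """One QM/MM-style S1 emission: energy/wavelength and oscillator strength."""

    snapshot_id: int
    conformer: Conformer
    emission_energy: float  # eV
    oscillator_strength: float

    def __post_init__(self) -> None:
        if self.emission_energy <= 0:
            raise ValueError("emission energy must be > 0 eV")
        if self.oscillator_strength < 0:
            raise ValueError("oscillator strength must be >= 0")

    @property
    def wavelength(self) -> float:
        """Emission wavelength in nm."""
        return EV_NM / self.emission_energy

    @classmethod
    def from_wavelength(
        cls, snapshot_id: int, conformer: Conformer, wavelength: float, f: float
    ) -> "EmissionRecord":
        if wavelength <= 0:
            raise ValueError("wavelength must be > 0 nm")
        return cls(snapshot_id, conformer, EV_NM / wavelength, f)


@dataclass
class Curve:
    """A time-binned curve: intensity decay or anisotropy, optional IRF."""

    t: np.ndarray
    y: np.ndarray
    kind: Literal["intensity", "anisotropy"]
    irf: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.kind == "intensity" and np.any(self.y < 0):
            raise ValueError("intensity must be >= 0")
        if self.kind not in ("intensity", "anisotropy"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
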