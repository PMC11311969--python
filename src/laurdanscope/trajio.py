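"""Readers and writers for the coordinate dialect, emission tables and curves.

Coordinate files use a GRO-style fixed-column layout (positions in nm), one
block per frame::

    <title line containing "t= <time>">
    <n_atoms>
    <resid:5d><resname:<5s><atomname:>5s><serial:5d><x:11.6f><y:11.6f><z:11.6f>
    ...
    <box_x> <box_y> <box_z>

Atom-name conventions (configurable through ``AtomNames``):

* DPPC lipid: ``P`` phosphorus; sn-1 carbons ``C<k>A`` with hydrogens
  ``H<k>A1``/``H<k>A2``; sn-2 carbons ``C<k>B`` with ``H<k>B1``/``H<k>B2``,
  ordered glycerol to terminal methyl.
* LAUR probe: ``HEAD`` head-group COM; ``TDMX``/``AXSX`` anchors placed 1 nm
  from HEAD along the transition dipole and the long molecular axis (never
  wrapped, so the unit vectors survive the round trip); ``OCB`` carbonyl
  oxygen; ``NAM`` amino nitrogen; tail carbons ``C<k>T`` with ``H<k>T1``/``2``.
* SOL water: ``OW``, ``HW1``, ``HW2``.

A YAML sidecar carries temperature, conformer, frame spacing and the
excitation time. Columns are wide enough (six decimals) that a write/read
round trip is the identity to 1e-6 nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (
    EV_NM,
    Curve,
    EmissionRecord,
    LipidRecord,
    ProbeRecord,
    Snapshot,
    Trajectory,
    TrajectoryMeta,
    WaterRecord,
)

CH_BOND = 0.109  # nm, written C-H bond length for stored unit vectors
ANCHOR_LEN = 1.0  # nm, HEAD -> TDMX/AXSX anchor distance


class TrajectoryParseError(ValueError):
    pass


@dataclass(frozen=True)
class AtomNames:
    """Mapping from structural roles to atom names in the coordinate file."""

    phosphorus: str = "P"
    water_o: str = "OW"
    water_h1: str = "HW1"
    water_h2: str = "HW2"
    head: str = "HEAD"
    tdm_anchor: str = "TDMX"
    axis_anchor: str = "AXSX"
    carbonyl_o: str = "OCB"
    amino_n: str = "NAM"
    lipid_resname: str = "DPPC"
    probe_resname: str = "LAUR"
    water_resname: str = "SOL"


DEFAULT_NAMES = AtomNames()

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


# ---------------------------------------------------------------- sidecar


def read_meta(path) -> TrajectoryMeta:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return TrajectoryMeta(
        temperature=float(d["temperature"]),
        conformer=str(d["conformer"]),
        dt=float(d["dt"]),
        excitation_time=float(d.get("excitation_time", 0.0)),
    )


def write_meta(meta: TrajectoryMeta, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "temperature": meta.temperature,
                "conformer": meta.conformer,
                "dt": meta.dt,
                "excitation_time": meta.excitation_time,
            },
            fh,
        )


# ---------------------------------------------------------------- writing


def _fmt_atom(resid: int, resname: str, name: str, serial: int, pos) -> str:
    return (
        f"{resid % 100000:5d}{resname:<5s}{name:>5s}{serial % 100000:5d}"
        f"{pos[0]:11.6f}{pos[1]:11.6f}{pos[2]:11.6f}\n"
    )


def _validate_finite(traj: Trajectory) -> None:
    for i, snap in enumerate(traj.frames):
        arrs = [snap.box]
        for l in snap.lipids:
            arrs += [l.phosphorus_pos, l.sn1_carbons, l.sn1_ch, l.sn2_carbons, l.sn2_ch]
        if snap.probe is not None:
            p = snap.probe
            arrs += [p.head_com, p.tdm, p.long_axis, p.carbonyl_o_pos, p.amino_n_pos,
                     p.tail_carbons, p.tail_ch]
        for w in snap.waters:
            arrs += [w.o_pos, w.h1_pos, w.h2_pos]
        for a in arrs:
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite coordinate in frame {i}")


def write_trajectory(traj: Trajectory, path, meta_path=None,
                     names: AtomNames = DEFAULT_NAMES) -> None:
    """Write a trajectory to the GRO-style dialect; optionally write the sidecar."""
    _validate_finite(traj)
    path = Path(path)
    with open(path, "w") as fh:
        if not traj.frames:
            fh.write("laurdanscope trajectory, 0 frames\n")
        for snap in traj.frames:
            lines: list[str] = []
            serial = 0
            resid = 0

            def emit(resname: str, name: str, pos) -> None:
                nonlocal serial
                serial += 1
                lines.append(_fmt_atom(resid, resname, name, serial, pos))

            for lip in snap.lipids:
                resid += 1
                emit(names.lipid_resname, names.phosphorus, lip.phosphorus_pos)
                for tail, carbons, ch in (("A", lip.sn1_carbons, lip.sn1_ch),
                                          ("B", lip.sn2_carbons, lip.sn2_ch)):
                    for k in range(len(carbons)):
                        emit(names.lipid_resname, f"C{k + 1}{tail}", carbons[k])
                        for h in range(ch.shape[1]):
                            emit(names.lipid_resname, f"H{k + 1}{tail}{h + 1}",
                                 carbons[k] + CH_BOND * ch[k, h])
            if snap.probe is not None:
                p = snap.probe
                resid += 1
                emit(names.probe_resname, names.head, p.head_com)
                emit(names.probe_resname, names.tdm_anchor,
                     p.head_com + ANCHOR_LEN * p.tdm)
                emit(names.probe_resname, names.axis_anchor,
                     p.head_com + ANCHOR_LEN * p.long_axis)
                emit(names.probe_resname, names.carbonyl_o, p.carbonyl_o_pos)
                emit(names.probe_resname, names.amino_n, p.amino_n_pos)
                for k in range(len(p.tail_carbons)):
                    emit(names.probe_resname, f"C{k + 1}T", p.tail_carbons[k])
                    for h in range(p.tail_ch.shape[1]):
                        emit(names.probe_resname, f"H{k + 1}T{h + 1}",
                             p.tail_carbons[k] + CH_BOND * p.tail_ch[k, h])
            for w in snap.waters:
                resid += 1
                emit(names.water_resname, names.water_o, w.o_pos)
                emit(names.water_resname, names.water_h1, w.h1_pos)
                emit(names.water_resname, names.water_h2, w.h2_pos)

            fh.write(f"laurdanscope frame t= {snap.time:.6f} ns\n")
            fh.write(f"{len(lines)}\n")
            fh.writelines(lines)
            fh.write(f"{snap.box[0]:11.6f}{snap.box[1]:11.6f}{snap.box[2]:11.6f}\n")
    if meta_path is not None:
        write_meta(traj.meta, meta_path)


# ---------------------------------------------------------------- reading


_CARBON_RE = re.compile(r"^C(\d+)([ABT])$")
_HYDRO_RE = re.compile(r"^H(\d+)([ABT])(\d)$")


def _parse_atom_line(line: str, frame: int, lineno: int):
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        x = float(line[20:31])
        y = float(line[31:42])
        z = float(line[42:53])
    except (ValueError, IndexError) as exc:
        raise TrajectoryParseError(
            f"frame {frame}: malformed atom line {lineno}: {line.rstrip()!r}"
        ) from exc
    return resid, resname, name, np.array([x, y, z])


def _build_chain(atoms: dict, tail: str, frame: int, resid: int):
    """Collect C<k><tail>/H<k><tail><j> atoms into carbon and C-H arrays."""
    ks = sorted(key[1] for key in atoms
                if len(key) == 3 and key[0] == "C" and key[2] == tail)
    carbons, ch = [], []
    for idx, k in enumerate(ks, start=1):
        if k != idx:
            raise TrajectoryParseError(
                f"frame {frame}: residue {resid} tail {tail} missing carbon {idx}")
        cpos = atoms[("C", k, tail)]
        hpos = []
        j = 1
        while ("H", k, tail, j) in atoms:
            hpos.append(atoms[("H", k, tail, j)])
            j += 1
        if not hpos:
            raise TrajectoryParseError(
                f"frame {frame}: residue {resid} carbon C{k}{tail} has no hydrogens")
        vecs = [(h - cpos) / np.linalg.norm(h - cpos) for h in hpos]
        carbons.append(cpos)
        ch.append(vecs)
    n_h = {len(v) for v in ch}
    if len(n_h) > 1:
        raise TrajectoryParseError(
            f"frame {frame}: residue {resid} tail {tail}: unequal hydrogen counts")
    return np.array(carbons), np.array(ch) if ch else np.zeros((0, 2, 3))


def _finish_residue(resname, resid, atoms, frame, names, out):
    if resname == names.lipid_resname:
        if ("named", names.phosphorus) not in atoms:
            raise TrajectoryParseError(
                f"frame {frame}: lipid residue {resid} missing atom "
                f"{names.phosphorus!r}")
        sn1_c, sn1_ch = _build_chain(atoms, "A", frame, resid)
        sn2_c, sn2_ch = _build_chain(atoms, "B", frame, resid)
        out["lipids_raw"].append(
            (atoms[("named", names.phosphorus)], sn1_c, sn1_ch, sn2_c, sn2_ch))
    elif resname == names.probe_resname:
        for key in (names.head, names.tdm_anchor, names.axis_anchor,
                    names.carbonyl_o, names.amino_n):
            if ("named", key) not in atoms:
                raise TrajectoryParseError(
                    f"frame {frame}: probe residue {resid} missing atom {key!r}")
        head = atoms[("named", names.head)]
        tdm = atoms[("named", names.tdm_anchor)] - head
        axis = atoms[("named", names.axis_anchor)] - head
        has_tail = any(len(k) == 3 and k[0] == "C" and k[2] == "T"
                       for k in atoms)
        tail_c, tail_ch = (_build_chain(atoms, "T", frame, resid) if has_tail
                           else (np.zeros((0, 3)), np.zeros((0, 2, 3))))
        out["probe"] = ProbeRecord(
            head_com=head,
            tdm=tdm / np.linalg.norm(tdm),
            long_axis=axis / np.linalg.norm(axis),
            carbonyl_o_pos=atoms[("named", names.carbonyl_o)],
            amino_n_pos=atoms[("named", names.amino_n)],
            tail_carbons=tail_c,
            tail_ch=tail_ch,
        )
    elif resname == names.water_resname:
        missing = [n for n in (names.water_o, names.water_h1, names.water_h2)
                   if ("named", n) not in atoms]
        if missing:
            raise TrajectoryParseError(
                f"frame {frame}: water residue {resid} missing atom(s) {missing}")
        out["waters"].append(WaterRecord(
            o_pos=atoms[("named", names.water_o)],
            h1_pos=atoms[("named", names.water_h1)],
            h2_pos=atoms[("named", names.water_h2)],
        ))
    else:
        raise TrajectoryParseError(
            f"frame {frame}: unknown residue name {resname!r}")


def _assemble_snapshot(time, box, out, frame) -> Snapshot:
    lipids = []
    raw = out["lipids_raw"]
    if raw:
        zs = np.array([r[0][2] for r in raw])
        mid = 0.5 * (zs.max() + zs.min())
        for p_pos, sn1_c, sn1_ch, sn2_c, sn2_ch in raw:
            leaflet = "upper" if p_pos[2] >= mid else "lower"
            lipids.append(LipidRecord(p_pos, leaflet, sn1_c, sn1_ch, sn2_c, sn2_ch))
    return Snapshot(time=time, box=box, lipids=lipids,
                    probe=out["probe"], waters=out["waters"])


def read_trajectory(path, meta_path, names: AtomNames = DEFAULT_NAMES) -> Trajectory:
    """Read a multi-frame coordinate file plus its metadata sidecar."""
    meta = read_meta(meta_path)
    frames: list[Snapshot] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    # a lone header line is an empty (0-frame) trajectory
    if len(lines) == 1 and not lines[0].strip().isdigit():
        return Trajectory(meta=meta, frames=[])
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else frame_idx * meta.dt
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError):
            if frame_idx > 0 and i >= len(lines) - 1:
                break
            raise TrajectoryParseError(
                f"frame {frame_idx}: expected atom count after title line")
        atom_lines = lines[i + 2: i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise TrajectoryParseError(f"frame {frame_idx}: truncated atom block")
        box_line = lines[i + 2 + natoms]
        box = np.array([float(v) for v in box_line.split()[:3]])

        out = {"lipids_raw": [], "probe": None, "waters": []}
        cur_resid: Optional[int] = None
        cur_resname = ""
        atoms: dict = {}
        for j, line in enumerate(atom_lines):
            resid, resname, name, pos = _parse_atom_line(line, frame_idx, i + 3 + j)
            if cur_resid is not None and (resid != cur_resid or resname != cur_resname):
                _finish_residue(cur_resname, cur_resid, atoms, frame_idx, names, out)
                atoms = {}
            cur_resid, cur_resname = resid, resname
            cm = _CARBON_RE.match(name)
            hm = _HYDRO_RE.match(name)
            if cm:
                atoms[("C", int(cm.group(1)), cm.group(2))] = pos
            elif hm:
                atoms[("H", int(hm.group(1)), hm.group(2), int(hm.group(3)))] = pos
            else:
                atoms[("named", name)] = pos
        if cur_resid is not None:
            _finish_residue(cur_resname, cur_resid, atoms, frame_idx, names, out)
        frames.append(_assemble_snapshot(time, box, out, frame_idx))
        i = i + 3 + natoms
        frame_idx += 1

    times = np.array([f.time for f in frames])
    if len(times) > 2:
        dts = np.diff(times)
        if np.ptp(dts) > 1e-6:
            raise TrajectoryParseError("non-uniform frame spacing in trajectory")
    return Trajectory(meta=meta, frames=frames)


# ------------------------------------------------------------ emission I/O


def read_emission_table(path) -> list[EmissionRecord]:
    """Read a TSV of per-snapshot S1 emissions.

    Recognised columns: ``snapshot_id``, ``conformer``, and at least one of
    ``emission_energy_ev`` / ``wavelength_nm`` (reconciled through
    E[eV] = 1239.84193 / lambda[nm]), plus ``oscillator_strength``.
    """
    df = pd.read_csv(path, sep="\t")
    has_e = "emission_energy_ev" in df.columns
    has_l = "wavelength_nm" in df.columns
    if not (has_e or has_l):
        raise ValueError("emission table needs emission_energy_ev or wavelength_nm")
    records = []
    for idx, row in df.iterrows():
        if has_e and not (has_l and pd.isna(row.get("emission_energy_ev"))):
            energy = float(row["emission_energy_ev"])
            if has_l and not pd.isna(row["wavelength_nm"]):
                implied = EV_NM / float(row["wavelength_nm"])
                if abs(implied - energy) / energy > 1e-3:
                    raise ValueError(
                        f"row {idx}: energy {energy} eV and wavelength "
                        f"{row['wavelength_nm']} nm disagree beyond 0.1%")
        else:
            energy = EV_NM / float(row["wavelength_nm"])
        records.append(EmissionRecord(
            snapshot_id=int(row["snapshot_id"]),
            conformer=str(row["conformer"]),
            emission_energy=energy,
            oscillator_strength=float(row["oscillator_strength"]),
        ))
    return records


def write_emission_table(records: Sequence[EmissionRecord], path) -> None:
    df = pd.DataFrame({
        "snapshot_id": [r.snapshot_id for r in records],
        "conformer": [r.conformer for r in records],
        "emission_energy_ev": [r.emission_energy for r in records],
        "wavelength_nm": [r.wavelength for r in records],
        "oscillator_strength": [r.oscillator_strength for r in records],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ------------------------------------------------------------ curve I/O


def read_curve(path, kind: str = "intensity") -> Curve:
    """Read a TSV curve: columns t_ns, value [, irf_t_ns, irf_value]."""
    df = pd.read_csv(path, sep="\t")
    irf = None
    if "irf_t_ns" in df.columns and "irf_value" in df.columns:
        mask = ~df["irf_t_ns"].isna()
        irf = (df.loc[mask, "irf_t_ns"].to_numpy(),
               df.loc[mask, "irf_value"].to_numpy())
    return Curve(t=df["t_ns"].to_numpy(), y=df["value"].to_numpy(),
                 kind=kind, irf=irf)


def write_curve(curve: Curve, path) -> None:
    cols = {"t_ns": curve.t, "value": curve.y}
    df = pd.DataFrame(cols)
    if curve.irf is not None:
        it, iy = curve.irf
        irf_df = pd.DataFrame({"irf_t_ns": it, "irf_value": iy})
        df = pd.concat([df, irf_df], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
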