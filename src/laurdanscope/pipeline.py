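"""Stage runner: wires the analysis modules into a reproducible report.

A config (YAML mapping, see ``run_pipeline``) names the inputs and the
enabled stages; every stage writes delimited tables into the output
directory and contributes to ``summary.json``, which echoes the config and
seed so a report is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import geometry, hydration, membrane, photophysics
from .records import Trajectory
from .synthetic import SynthParams, generate_emission_table, generate_trajectory
from .trajio import (read_emission_table, read_curve, read_trajectory,
                     write_emission_table, write_trajectory)

VALID_STAGES = ("synth", "geometry", "hydration", "phase", "apl",
                "optics", "fit", "all")


class ConfigError(ValueError):
    pass


def _fmt(x) -> float:
    return float(np.round(x, 10))


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Run the enabled stages and write the report bundle.

    Config keys::

        stages: [synth | geometry | hydration | phase | apl | optics | fit | all]
        inputs:
          trajectory: coords file      trajectory_meta: sidecar
          emission_table: TSV          decay_curve: TSV
          anisotropy_curve: TSV
        synth: {SynthParams field overrides}
        hydration: {radius, r_max, dr}
        optics: {fwhm, weight}
        fit: {n_components, irf: [mean, sigma]}

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    if not stages:
        raise ConfigError("no stages enabled")
    for s in stages:
        if s not in VALID_STAGES:
            raise ConfigError(
                f"unknown stage {s!r}; valid stages: {', '.join(VALID_STAGES)}")
    fit_explicit = "fit" in stages
    if "all" in stages:
        stages = ["synth", "geometry", "hydration", "phase", "optics", "fit"]

    inputs = config.get("inputs", {}) or {}
    needs_traj = any(s in stages for s in
                     ("geometry", "hydration", "phase", "apl"))
    needs_emission = "optics" in stages
    if needs_traj and "trajectory" not in inputs and "synth" not in stages:
        raise ConfigError("config names no trajectory input and no synth stage")
    if needs_emission and "emission_table" not in inputs \
            and "synth" not in stages:
        raise ConfigError("config names no emission input and no synth stage")
    if not inputs and "synth" not in stages:
        raise ConfigError("config has no inputs and no synth stage")

    summary: dict = {"config": config, "seed": seed, "stages": stages,
                     "outputs": []}

    traj: Optional[Trajectory] = None
    emission = None
    if "synth" in stages:
        overrides = dict(config.get("synth", {}))
        overrides["seed"] = seed
        params = SynthParams(**overrides)
        traj = generate_trajectory(params)
        emission = generate_emission_table(params, config.get(
            "synth_n_records", 50))
        write_trajectory(traj, out / "trajectory.gro", out / "trajectory.yaml")
        write_emission_table(emission, out / "emission.tsv")
        truth = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(params).items()}
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        summary["outputs"] += ["trajectory.gro", "emission.tsv",
                               "ground_truth.json"]
    if traj is None and "trajectory" in inputs:
        traj = read_trajectory(inputs["trajectory"], inputs["trajectory_meta"])
    if emission is None and "emission_table" in inputs:
        emission = read_emission_table(inputs["emission_table"])

    if "geometry" in stages:
        dist = geometry.angle_distribution(traj, "tdm")
        pd.DataFrame({
            "angle_deg": 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:]),
            "count": dist.counts,
        }).to_csv(out / "tdm_angle_hist.tsv", sep="\t", index=False)
        prof = geometry.depth_profile(traj)
        pd.DataFrame(
            {"z_nm": 0.5 * (prof.z_bins[:-1] + prof.z_bins[1:]),
             **{k: v for k, v in prof.density.items()}}
        ).to_csv(out / "depth_profile.tsv", sep="\t", index=False,
                 float_format="%.8g")
        summary["geometry"] = {
            "tdm_mode_deg": _fmt(dist.mode_angle),
            "tdm_hwhm_deg": _fmt(dist.hwhm),
            "tdm_mode_drift_deg": _fmt(dist.mode_drift),
            "mean_p_distance_nm": _fmt(prof.mean_p_distance),
        }
        summary["outputs"] += ["tdm_angle_hist.tsv", "depth_profile.tsv"]

    if "hydration" in stages:
        hcfg = config.get("hydration", {}) or {}
        rdf = hydration.water_rdf(traj, r_max=hcfg.get("r_max", 1.2),
                                  dr=hcfg.get("dr", 0.02))
        pd.DataFrame({"r_nm": rdf.r_bins, "g": rdf.g,
                      "coordination": rdf.coordination}).to_csv(
            out / "water_rdf.tsv", sep="\t", index=False, float_format="%.8g")
        series = hydration.cumulative_solvent_orientation(
            traj, radius=hcfg.get("radius", 1.0))
        pd.DataFrame({
            "window_start_ns": [w[0] for w in series.windows],
            "window_end_ns": [w[1] for w in series.windows],
            "cumulative_orientation": series.values,
        }).to_csv(out / "solvent_orientation.tsv", sep="\t", index=False,
                  float_format="%.8g")
        fit = hydration.fit_solvent_relaxation(series)
        summary["hydration"] = {
            "relax_time_ns": _fmt(fit.relax_time) if fit.converged else None,
            "asymptote": _fmt(fit.asymptote),
            "converged": fit.converged,
        }
        summary["outputs"] += ["water_rdf.tsv", "solvent_orientation.tsv"]

    if "phase" in stages or "apl" in stages:
        series, mean_apl = membrane.area_per_lipid(traj)
        pd.DataFrame({"frame": np.arange(len(series)),
                      "apl_A2": series}).to_csv(
            out / "apl.tsv", sep="\t", index=False, float_format="%.8g")
        summary["apl"] = {"mean_A2": _fmt(mean_apl)}
        summary["outputs"].append("apl.tsv")
        if "phase" in stages:
            rows = []
            for tail in ("sn1", "sn2"):
                prof = membrane.deuterium_order_parameters(traj, tail)
                for k, s in enumerate(prof.s_cd, start=1):
                    rows.append({"tail": tail, "carbon": k, "s_cd": s})
            pd.DataFrame(rows).to_csv(out / "order_parameters.tsv", sep="\t",
                                      index=False, float_format="%.8g")
            tmap = membrane.thickness_map(traj.frames[-1],
                                          config.get("cell_size", 0.8))
            xs = 0.5 * (tmap.x_edges[:-1] + tmap.x_edges[1:])
            ys = 0.5 * (tmap.y_edges[:-1] + tmap.y_edges[1:])
            recs = [{"x_nm": xs[i], "y_nm": ys[j],
                     "thickness_nm": tmap.grid[i, j],
                     "interpolated": bool(tmap.fill_mask[i, j])}
                    for i in range(len(xs)) for j in range(len(ys))]
            pd.DataFrame(recs).to_csv(out / "thickness_map.tsv", sep="\t",
                                      index=False, float_format="%.8g")
            ripple = membrane.ripple_metrics(tmap)
            sn1 = membrane.deuterium_order_parameters(traj, "sn1")
            call = membrane.classify_phase(
                mean_apl, membrane.plateau_scd(sn1),
                0.0 if ripple.flagged else ripple.rms)
            summary["phase"] = {
                "label": call.label,
                "apl_A2": _fmt(call.apl),
                "scd_plateau": _fmt(call.scd_plateau),
                "ripple_rms_nm": None if ripple.flagged else _fmt(ripple.rms),
                "ripple_wavelength_nm": (
                    None if ripple.dominant_wavelength is None
                    else _fmt(ripple.dominant_wavelength)),
            }
            summary["outputs"] += ["order_parameters.tsv", "thickness_map.tsv"]

    if "optics" in stages:
        ocfg = config.get("optics", {}) or {}
        spec = photophysics.convolve_spectrum(
            emission, fwhm=ocfg.get("fwhm", 15.0),
            weight=ocfg.get("weight", "oscillator_strength"))
        df = pd.DataFrame({"wavelength_nm": spec.wavelength_grid,
                           "intensity": spec.intensity})
        for conf, comp in spec.components.items():
            df[f"intensity_conf_{conf}"] = comp
        df.to_csv(out / "spectrum.tsv", sep="\t", index=False,
                  float_format="%.8g")
        peak, shoulders = photophysics.find_peak_and_shoulders(spec)
        taus = {c: [photophysics.radiative_lifetime(r) for r in emission
                    if r.conformer == c]
                for c in sorted({r.conformer for r in emission})}
        summary["optics"] = {
            "peak_nm": None if peak is None else _fmt(peak),
            "shoulders_nm": [_fmt(s["wavelength_nm"]) for s in shoulders],
            "gp": _fmt(photophysics.gp_from_spectrum(spec))
            if spec.wavelength_grid[0] <= 430 and spec.wavelength_grid[-1] >= 500
            else None,
            "mean_radiative_lifetime_ns": {
                c: _fmt(np.mean(v)) for c, v in taus.items()},
        }
        summary["outputs"].append("spectrum.tsv")

    if "fit" in stages:
        fcfg = config.get("fit", {}) or {}
        if "decay_curve" in inputs:
            curve = read_curve(inputs["decay_curve"], kind="intensity")
            irf = fcfg.get("irf")
            res = photophysics.fit_exponential_decay(
                curve, n_components=fcfg.get("n_components", 1),
                irf=None if irf is None else tuple(irf))
            summary["fit"] = {
                "lifetimes_ns": [_fmt(x) for x in res.lifetimes],
                "intensity_fractions_pct": [_fmt(x)
                                            for x in res.intensity_fractions],
                "reduced_chi_square": _fmt(res.goodness),
                "converged": res.converged,
            }
        if "anisotropy_curve" in inputs:
            rcurve = read_curve(inputs["anisotropy_curve"], kind="anisotropy")
            amp, theta, off, _ = photophysics.fit_anisotropy_exponential(rcurve)
            summary.setdefault("fit", {})["anisotropy"] = {
                "amplitude": _fmt(amp), "time_constant_ns": _fmt(theta),
                "offset": _fmt(off)}
        if "fit" not in summary and fit_explicit:
            raise ConfigError("fit stage enabled but no curve inputs given")

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return summary
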