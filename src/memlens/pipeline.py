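"""Configuration-driven orchestration of the full analysis sweep.

A single YAML config describes the systems (synthetic specs or trajectory
paths), which stages to run and per-stage parameter overrides; the pipeline
executes stages in dependency order (generate -> membrane metrics / cluster
/ rdf -> pmf -> thermo -> msd), writes per-stage TSVs and a consolidated
one-row-per-system summary. Every output embeds the config hash and seed so
a sweep is reproducible from the config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, dynamics, membrane, pairs, synthetic, thermo
from .core import Trajectory, read_trajectory
from .synthetic import (LayeringField, PairPotential, SamplerConfig,
                        SyntheticSpec)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

ALL_ANALYSES = ("apl", "vpl", "thickness", "density", "ka", "cluster",
                "rdf", "pmf", "minima", "split", "thermo", "msd",
                "diffusion")


@dataclass
class PipelineConfig:
    systems: list                    # list of dicts (see load_config)
    analyses: tuple = ALL_ANALYSES
    params: dict = field(default_factory=dict)
    outdir: str = "memlens_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(
            {"systems": self.systems, "analyses": list(self.analyses),
             "params": self.params, "seed": self.seed},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _spec_from_dict(d: dict, seed: int) -> SyntheticSpec:
    d = dict(d)
    if "pair_potential" in d:
        d["pair_potential"] = PairPotential(**d["pair_potential"])
    if d.get("layering_field") is not None:
        d["layering_field"] = LayeringField(**d["layering_field"])
    if "sampler" in d:
        d["sampler"] = SamplerConfig(**{k: (tuple(v) if k == "axes" else v)
                                        for k, v in d["sampler"].items()})
    if "box" in d:
        d["box"] = tuple(d["box"])
    d.setdefault("seed", seed)
    return SyntheticSpec(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    systems = raw.get("systems", [])
    for sysdef in systems:
        if "trajectory" in sysdef:
            for key in ("trajectory", "topology"):
                if key not in sysdef:
                    raise ValueError(f"system {sysdef.get('name')}: needs "
                                     f"'{key}'")
                if not Path(sysdef[key]).exists():
                    raise FileNotFoundError(sysdef[key])
        elif "generate" not in sysdef:
            raise ValueError("each system needs 'generate' or 'trajectory'")
    return PipelineConfig(
        systems=systems,
        analyses=tuple(raw.get("analyses", ALL_ANALYSES)),
        params=raw.get("params", {}),
        outdir=raw.get("outdir", "memlens_out"),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"))


def _materialize(sysdef: dict, seed: int, outdir: Path):
    """Load or generate the system's trajectory; returns (traj, spec)."""
    if "trajectory" in sysdef:
        return read_trajectory(sysdef["trajectory"], sysdef["topology"],
                               top=sysdef.get("top")), None
    spec = _spec_from_dict(sysdef["generate"], seed)
    parts = None
    if spec.n_particles > 0:
        if spec.sampler.mode == "brownian":
            parts = synthetic.simulate_brownian(spec)
        else:
            parts = synthetic.sample_particles_mc(spec)
    if spec.n_lipids > 0:
        mem = synthetic.generate_slab_membrane(
            spec if parts is None
            else spec.replace(n_frames=1))
        traj = mem if parts is None else synthetic.combine(mem, parts)
    else:
        traj = parts
    if traj is None:
        raise ValueError("system generates neither lipids nor particles")
    name = sysdef.get("name", "system")
    synthetic.write_system(traj, outdir / f"{name}.gro",
                           outdir / f"{name}.topmap.yaml")
    return traj, spec


def _tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all requested stages for every system; returns the summary table.

    Stage failures abort that system's dependent stages only; partial
    results are preserved and the failure recorded in the summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    head = [f"memlens config_hash={chash} seed={config.seed}"]
    p = config.params
    temperature = float(p.get("temperature", 298.0))
    rows = []
    for sysdef in config.systems:
        name = sysdef.get("name", f"system{len(rows)}")
        row: dict = {"system": name, "config_hash": chash,
                     "seed": config.seed, "error": ""}
        try:
            traj, spec = _materialize(sysdef, config.seed, outdir)
        except Exception as exc:
            log.error("system %s: generation failed: %s", name, exc)
            row["error"] = f"generate: {exc}"
            rows.append(row)
            continue
        if spec is not None and spec.n_lipids:
            row["np_per_lipid"] = spec.n_particles / spec.n_lipids
        row.update(_analyze_system(name, traj, config, outdir, head,
                                   temperature, spec))
        rows.append(row)
    summary = pd.DataFrame(rows)
    _tsv(summary, outdir / "summary.tsv", head)
    summary.to_json(outdir / "summary.json", orient="records", indent=2)
    return summary


def _analyze_system(name: str, traj: Trajectory, config: PipelineConfig,
                    outdir: Path, head: list[str],
                    temperature: float, spec=None) -> dict:
    p = config.params
    want = set(config.analyses)
    row: dict = {}
    errors = []

    def attempt(stage, fn):
        if stage not in want:
            return None
        try:
            return fn()
        except Exception as exc:  # stage isolation is the contract here
            log.warning("system %s stage %s failed: %s", name, stage, exc)
            errors.append(f"{stage}: {exc}")
            return None

    apl = attempt("apl", lambda: membrane.area_per_lipid(traj))
    if apl is not None:
        row["apl_nm2"], row["apl_sd"] = apl.mean, apl.sd
    vpl = attempt("vpl", lambda: membrane.volume_per_lipid(
        traj, water_bead_volume=float(p.get("water_bead_volume", 0.12))))
    if vpl is not None:
        row["vpl_nm3"], row["vpl_sd"] = vpl.mean, vpl.sd

    prof = attempt("density", lambda: membrane.density_profile(
        traj, groups=p.get("density_groups",
                           ["lipid_head", "lipid_tail", "fullerene"]),
        bin_width=float(p.get("density_bin_width", 0.1))))
    if prof is not None:
        df = pd.DataFrame({"z_nm": prof.z_grid,
                           **{f"rho_{g}_amu_nm3": v
                              for g, v in prof.density.items()}})
        _tsv(df, outdir / f"{name}.density.tsv",
             head + [f"bin_width={prof.bin_width} n_frames={prof.n_frames}"])
    if "thickness" in want:
        src = prof
        if src is None:
            src = attempt("thickness", lambda: membrane.density_profile(
                traj, groups=["lipid_head"],
                bin_width=float(p.get("density_bin_width", 0.1))))
        th = (attempt("thickness", lambda: membrane.bilayer_thickness(src))
              if src is not None else None)
        if th is not None:
            row["thickness_nm"] = th

    ka = attempt("ka", lambda: membrane.area_compressibility(
        traj.boxes[:, 0] * traj.boxes[:, 1], temperature))
    if ka is not None:
        row["ka_kJ_mol_nm2"], row["ka_err"] = ka

    window = float(p.get("window_fraction", 0.5))
    cl = attempt("cluster", lambda: aggregation.largest_cluster_series(
        traj, cutoff=float(p.get("cutoff", aggregation.DEFAULT_CUTOFF)),
        window_fraction=window))
    if cl is not None:
        row["mean_largest_cluster"] = cl.mean_largest
        row["sd_largest_cluster"] = cl.sd_largest
        row["fraction_in_largest"] = cl.mean_fraction
        df = pd.DataFrame({"frame": cl.frames, "largest_size": cl.largest_size,
                           "n_clusters": cl.n_clusters,
                           "fraction_in_largest": cl.fraction_in_largest})
        _tsv(df, outdir / f"{name}.cluster.tsv",
             head + [f"cutoff_nm={cl.cutoff} window_fraction={window}"])

    rdf_kwargs = dict(
        bin_width=float(p.get("rdf_bin_width", 0.02)),
        mode=p.get("rdf_mode", "plateau_normalized"),
        plateau_window=tuple(p.get("plateau_window", (2.5, 3.2))),
        window_fraction=window)
    if p.get("r_max") is not None:
        rdf_kwargs["r_max"] = float(p["r_max"])
    pd_ = attempt("rdf", lambda: pairs.com_rdf(traj, **rdf_kwargs))
    fep = None
    if pd_ is not None:
        df = pd.DataFrame({"r_nm": pd_.r_grid, "g": pd_.g,
                           "counts": pd_.counts})
        _tsv(df, outdir / f"{name}.rdf.tsv",
             head + [f"mode={pd_.mode} bin_width={pd_.bin_width} "
                     f"plateau_window={pd_.plateau_window}"])
        fep = attempt("pmf", lambda: pairs.free_energy_profile(
            pd_, temperature))
        if fep is not None:
            df = pd.DataFrame({"r_nm": fep.r_grid, "dG_kJ_mol": fep.dG,
                               "defined": fep.defined.astype(int)})
            _tsv(df, outdir / f"{name}.pmf.tsv",
                 head + [f"T={temperature}K {fep.reference}"])
        mins = (attempt("minima", lambda: pairs.locate_minima(fep))
                if fep is not None else None)
        if mins is not None:
            row.update(r_min1_nm=mins.r_min1, dG_min1_kJ_mol=mins.dG_min1,
                       r_min2_nm=mins.r_min2, dG_min2_kJ_mol=mins.dG_min2,
                       ddG_kJ_mol=mins.ddG)
        split = attempt("split", lambda: pairs.detect_second_peak_split(pd_))
        if split is not None:
            row["second_peak_split"] = split["split"]

    if "thermo" in want and spec is not None and spec.n_particles >= 2 \
            and spec.sampler.mode == "metropolis":
        temps = tuple(p.get("thermo_temperatures", (283.0, 298.0, 313.0)))

        def run_thermo():
            from . import thermo as thermo_mod
            trajs = [synthetic.sample_particles_mc(
                spec.replace(n_lipids=0, n_waters=0, temperature=t))
                for t in temps]
            return thermo_mod.decompose(*trajs, temperatures=temps,
                                        **rdf_kwargs)
        dec = attempt("thermo", run_thermo)
        if dec is not None:
            df = pd.DataFrame({"r_nm": dec.r_grid, "dG_kJ_mol": dec.dG,
                               "minus_TdS_kJ_mol": dec.minus_TdS,
                               "dH_kJ_mol": dec.dH,
                               "defined": dec.defined.astype(int)})
            _tsv(df, outdir / f"{name}.thermo.tsv",
                 head + [f"T={dec.temperature}K dT={dec.delta_T}K"])
            if dec.minima_minus_TdS is not None:
                row["minus_TdS_min1_kJ_mol"] = dec.minima_minus_TdS[0]
                row["minus_TdS_min2_kJ_mol"] = dec.minima_minus_TdS[1]
                row["dH_min1_kJ_mol"] = dec.minima_dH[0]
                row["dH_min2_kJ_mol"] = dec.minima_dH[1]

    if {"msd", "diffusion"} & want:
        def run_msd():
            un = dynamics.unwrap(traj)
            lat = dynamics.msd(un, axes=("x", "y"))
            nor = dynamics.msd(un, axes=("z",))
            return lat, nor
        curves = attempt("msd", run_msd)
        if curves is not None:
            lat, nor = curves
            df = pd.DataFrame({"lag_ns": lat.lag_times,
                               "msd_xy_nm2": lat.msd, "sem_xy": lat.sem,
                               "msd_z_nm2": nor.msd, "sem_z": nor.sem})
            _tsv(df, outdir / f"{name}.msd.tsv", head)
            if "diffusion" in want:
                import warnings as _w
                fitw = tuple(p.get("fit_window", (0.1, 0.5)))
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    dl = attempt("diffusion", lambda: dynamics.
                                 diffusion_coefficient(lat, 2, fitw))
                    dn = attempt("diffusion", lambda: dynamics.
                                 diffusion_coefficient(nor, 1, fitw))
                if dl is not None:
                    row["D_lateral_nm2_ns"] = dl.D
                    row["D_lateral_r2"] = dl.fit_r2
                if dn is not None:
                    row["D_normal_nm2_ns"] = dn.D
                    row["D_normal_r2"] = dn.fit_r2

    row["error"] = "; ".join(errors)
    return row
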