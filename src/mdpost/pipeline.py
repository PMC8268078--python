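"""Single-command analysis pipeline and report bundle.

A run configuration (YAML mapping or dict) names either an input system
(multi-model PDB + parameter sidecar + component map) or a synthetic
specification — never both — selects a frame window, and parameterizes the
analysis stages.  :func:`run_pipeline` then produces, per system:

* ``block_density.tsv`` / ``.json`` and ``cc_matrix.tsv`` — component-pair
  correlation densities and the full residue DCC matrix,
* ``rmsf.tsv`` — per-residue RMSF/B-factor profile,
* ``hbond_occupancy.tsv`` and ``hbond_network.json`` — occupancy table and
  the ≥ threshold network view,
* ``cluster_summary.json`` and ``cluster_rep_*.pdb`` — cluster sizes with
  representative (medoid) frames,
* ``energy_*`` tables per binding division — per-frame totals, per-residue
  and pairwise decompositions,

plus ``manifest.json`` recording package version, seed, config hash, the
frame window actually used, and per-stage status.  With several systems a
cross-system differential hydrogen-bond network is added.  Outputs are a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import ClusterConfig, agglomerative_cluster, pairwise_rmsd_matrix
from .correlation import block_correlation_density, \
    cross_correlation_matrix, residue_representative_series
from .gb import EnergyModelConfig, decompose, mmgbsa_binding, \
    partition_from_components
from .geometry import average_structure, fit_trajectory, rmsf, select_heavy
from .hbond import HBondConfig, differential_network, hbond_occupancy, \
    network_json
from .io import Trajectory, load_component_map, read_topology, \
    read_trajectory, write_table, write_trajectory
from .synthetic import SyntheticSpec, gaussian_block_trajectory

__all__ = ["PipelineError", "run_pipeline", "load_run_config"]

ALL_STAGES = ("correlate", "rmsf", "hbond", "cluster", "energy")


class PipelineError(RuntimeError):
    pass


def load_run_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return yaml.safe_load(fh)
    return dict(source)


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_system(config: dict, seed: int):
    has_input = "input" in config
    has_synth = "synthetic" in config
    if has_input == has_synth:
        raise PipelineError(
            "config must contain exactly one of 'input' or 'synthetic'")
    if has_input:
        inp = config["input"]
        topology = read_topology(inp["topology_pdb"], inp["params"])
        trajectory = read_trajectory(inp["trajectory"], topology)
        cmap = load_component_map(inp["component_map"], topology)
        return topology, trajectory, cmap
    s = dict(config["synthetic"])
    blocks = {}
    for key, rho in (s.get("block_correlations") or {}).items():
        a, b = key.split(":") if isinstance(key, str) else key
        blocks[(a, b)] = float(rho)
    spec = SyntheticSpec(
        components=[tuple(c) for c in s.get("components",
                                            [("A", 30, 1), ("B", 30, 1),
                                             ("C", 30, 1)])],
        block_correlations=blocks,
        fluctuation_sigma=float(s.get("fluctuation_sigma", 0.5)),
        n_frames=int(s.get("n_frames", 300)),
        seed=int(s.get("seed", seed)))
    result = gaussian_block_trajectory(spec)
    return result.topology, result.trajectory, result.component_map


def _apply_window(trajectory: Trajectory, config: dict) -> Trajectory:
    w = config.get("window")
    if not w:
        return trajectory
    if "last_n_frames" in w:
        return trajectory.last_n_frames(int(w["last_n_frames"]))
    if "last_ns" in w:
        return trajectory.last_time(float(w["last_ns"]))
    return trajectory.with_window(int(w.get("start", 0)),
                                  int(w.get("end", trajectory.n_frames)))


def run_pipeline(config, output_dir=None, stages=ALL_STAGES) -> dict:
    """Run the analysis bundle; returns the manifest dict."""
    config = load_run_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "mdpost_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    if "systems" in config:
        return _run_multi(config, outdir, stages, seed)

    manifest = {
        "mdpost_version": __version__,
        "seed": seed,
        "config_sha256": _config_hash(config),
        "stages": {},
        "artifacts": [],
    }
    stage = "load"
    try:
        topology, trajectory, cmap = _load_system(config, seed)
        trajectory = _apply_window(trajectory, config)
        manifest["window"] = list(trajectory.window)
        manifest["n_frames_total"] = trajectory.n_frames
        manifest["stages"]["load"] = "ok"

        stage = "fit"
        heavy = select_heavy(topology)
        masses = topology.masses[heavy]
        mean = average_structure(trajectory, heavy, masses)
        fitted = fit_trajectory(trajectory, mean, heavy, masses)
        manifest["stages"]["fit"] = "ok"

        for stage in stages:
            _STAGE_FUNCS[stage](config, outdir, manifest,
                                topology, fitted, trajectory, cmap, seed)
            manifest["stages"][stage] = "ok"
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        manifest["stages"][stage] = f"failed: {exc}"
        manifest["partial"] = True
        _write_manifest(outdir, manifest)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _emit(outdir, manifest, name, df, fmt="tsv", columns=None):
    path = outdir / name
    write_table(df, path, fmt, columns=columns)
    manifest["artifacts"].append(name)


def _stage_correlate(config, outdir, manifest, topology, fitted, raw, cmap,
                     seed):
    mode = (config.get("correlation") or {}).get("mode", "mass_center")
    series, res_idx = residue_representative_series(fitted, topology, mode)
    ccm = cross_correlation_matrix(series, topology, res_idx)
    dens = block_correlation_density(ccm, cmap)
    _emit(outdir, manifest, "cc_matrix.tsv",
          ccm.to_frame().reset_index(names="residue"))
    _emit(outdir, manifest, "block_density.tsv",
          dens.reset_index(names="component"))
    _emit(outdir, manifest, "block_density.json",
          dens.reset_index(names="component"), "json")


def _stage_rmsf(config, outdir, manifest, topology, fitted, raw, cmap, seed):
    profile = rmsf(fitted, topology)
    _emit(outdir, manifest, "rmsf.tsv", profile.to_records(),
          columns=["residue", "rmsf_A", "bfactor_A2"])


def _stage_hbond(config, outdir, manifest, topology, fitted, raw, cmap, seed):
    import pandas as pd

    hb = HBondConfig(**(config.get("hbond") or {}))
    if topology.bonds:
        table = hbond_occupancy(raw, topology, hb, cmap)
    else:  # no covalent bonds -> no donors; still emit the (empty) table
        table = pd.DataFrame(columns=["donor", "hydrogen", "acceptor",
                                      "occupancy_percent", "donor_index",
                                      "hydrogen_index", "acceptor_index",
                                      "window_start", "window_end"])
    _emit(outdir, manifest, "hbond_occupancy.tsv", table)
    view = table.assign(
        in_network=table["occupancy_percent"] >= hb.report_threshold) \
        .rename(columns={"occupancy_percent": "occupancy_percent:system"})
    net = network_json(view)
    with open(outdir / "hbond_network.json", "w") as fh:
        json.dump(net, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["artifacts"].append("hbond_network.json")


def _stage_cluster(config, outdir, manifest, topology, fitted, raw, cmap,
                   seed):
    opts = dict(config.get("cluster") or {})
    max_frames = int(opts.pop("max_frames", 60))
    cc = ClusterConfig(**opts)
    start, end = fitted.window
    length = end - start
    idx = np.unique(np.round(
        np.linspace(start, end - 1, min(max_frames, length))).astype(int))
    sub = Trajectory(fitted.coordinates[idx])
    dmat = pairwise_rmsd_matrix(sub, topology, cc)
    result = agglomerative_cluster(dmat, cc)
    summary = result.summary()
    summary["frame_indices"] = [int(i) for i in idx]
    summary["representative_frames"] = [int(idx[r])
                                        for r in result.representatives]
    with open(outdir / "cluster_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["artifacts"].append("cluster_summary.json")
    for c, r in enumerate(result.representatives):
        name = f"cluster_rep_{c}.pdb"
        write_trajectory(outdir / name, topology,
                         Trajectory(sub.coordinates[r:r + 1]))
        manifest["artifacts"].append(name)


def _stage_energy(config, outdir, manifest, topology, fitted, raw, cmap,
                  seed):
    opts = dict(config.get("energy") or {})
    divisions = opts.pop("partitions", None)
    if divisions is None:
        names = cmap.component_names
        if len(names) < 2:
            raise PipelineError("energy stage needs >= 2 components")
        divisions = [{"name": "binding",
                      "receptor": names[:1], "ligand": names[1:]}]
    cfg = EnergyModelConfig(**opts)
    for div in divisions:
        part = partition_from_components(topology, cmap,
                                         div["receptor"], div["ligand"])
        breakdown = mmgbsa_binding(raw, topology, part, cfg)
        tag = div.get("name", "binding")
        _emit(outdir, manifest, f"energy_{tag}_per_frame.tsv",
              breakdown.per_frame)
        _emit(outdir, manifest, f"energy_{tag}_per_residue.tsv",
              decompose(breakdown, "per_residue"))
        _emit(outdir, manifest, f"energy_{tag}_pairwise.tsv",
              decompose(breakdown, "pairwise"))


_STAGE_FUNCS = {
    "correlate": _stage_correlate,
    "rmsf": _stage_rmsf,
    "hbond": _stage_hbond,
    "cluster": _stage_cluster,
    "energy": _stage_energy,
}


def _run_multi(config, outdir, stages, seed):
    from .io import read_table

    manifest = {
        "mdpost_version": __version__,
        "seed": seed,
        "config_sha256": _config_hash(config),
        "systems": {},
        "artifacts": [],
    }
    tables = {}
    shared = {k: v for k, v in config.items() if k != "systems"}
    for sysconf in config["systems"]:
        name = sysconf["name"]
        sub = dict(shared)
        sub.update({k: v for k, v in sysconf.items() if k != "name"})
        sub_manifest = run_pipeline(sub, outdir / name, stages)
        manifest["systems"][name] = sub_manifest
        occ_path = outdir / name / "hbond_occupancy.tsv"
        if occ_path.exists():
            table = read_table(occ_path)
            if len(table):
                tables[name] = table
    if len(tables) >= 2:
        hb = HBondConfig(**(config.get("hbond") or {}))
        comparison = differential_network(tables, hb)
        write_table(comparison, outdir / "differential_network.tsv")
        with open(outdir / "differential_network.json", "w") as fh:
            json.dump(network_json(comparison), fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest["artifacts"] += ["differential_network.tsv",
                                  "differential_network.json"]
    _write_manifest(outdir, manifest)
    return manifest
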