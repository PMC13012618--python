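"""Config-driven orchestration of the analysis stages.

A pipeline is described by a YAML/dict config naming the stages to run and
their parameters; ``validate`` checks cross-references and ranges and echoes
the fully defaulted config, ``run`` executes the stages in order and writes
every product plus a deterministic JSON manifest (config snapshot, package
version, SHA-256 of every output).  Wall-clock timings and captured
warnings go to a sibling ``run.log`` so re-running an identical config
reproduces the manifest byte for byte.

All randomness flows from seeds recorded in the config; no stage reads
entropy elsewhere.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import contacts as contacts_mod
from . import free_energy as fe
from . import geometry as geo
from . import network as net
from . import synthetic as syn
from .model import FrameEnsemble, Topology, load_structure, load_trajectory, select, superpose

__all__ = ["PipelineConfig", "validate", "run", "load_config", "default_config"]

logger = logging.getLogger("allonet.pipeline")

KNOWN_STAGES = ("synth_ensemble", "synth_umbrella", "network", "paths",
                "communities", "contacts", "orderparams", "pca", "wham",
                "sensitivity", "report")

_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "allonet_out",
    "stages": ["synth_ensemble", "network", "paths", "communities", "report"],
    "ensemble": {
        "kind": "planted_path",        # planted_path | planted_partition
        "n_residues": 30,
        "n_frames": 5000,
        "sigma_nm": 0.02,
        "source": 5,
        "sink": 25,
        "n_intermediates": 4,
        "rho": 0.8,
        "rho_in": 0.5,
        "background_rho": 0.05,
    },
    "umbrella": {
        "potential": "harmonic",
        "params": {"kappa": 100.0, "xi0": 0.6},
        "windows": [round(x, 6) for x in np.linspace(0.3, 1.2, 10)],
        "spring_constant_kj_mol_nm2": 1500.0,
        "n_samples": 5000,
        "temperature_K": 310.0,
    },
    "network": {"cutoff_nm": 0.45, "persistence": 0.75, "k_neighbours": 7},
    "paths": {"source": None, "sink": None, "n_suboptimal": 20},
    "communities": {"seed": 0, "min_fraction": 0.01},
    "contacts": {"threshold_pp": 40.0, "classification_persistence": 0.5},
    "orderparams": {"torsion_groups": None, "distances": []},
    "pca": {"fit": "backbone", "n_components": 5},
    "wham": {"n_bins": 100, "tolerance_kt": 1e-8, "n_boot": 0,
             "states": {"close": [0.0, 0.4], "far": [0.65, 10.0]}},
    "sensitivity": {"cutoffs_nm": [0.42, 0.45, 0.48],
                    "persistences": [0.65, 0.75, 0.85]},
    "inputs": {"topology": None, "trajectory": None, "umbrella_meta": None},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with every default filled in."""

    data: dict
    failures: list[str] = field(default_factory=list)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def valid(self) -> bool:
        return not self.failures


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def validate(config: Optional[dict]) -> PipelineConfig:
    """Check stages, ranges and cross-stage dependencies; echo full defaults."""
    cfg = _merge(_DEFAULTS, config or {})
    failures: list[str] = []
    for stage in cfg["stages"]:
        if stage not in KNOWN_STAGES:
            failures.append(f"unknown stage {stage!r}")
    netc = cfg["network"]
    if not 0 < netc["persistence"] <= 1:
        failures.append(f"network.persistence {netc['persistence']} outside (0, 1]")
    if netc["cutoff_nm"] <= 0:
        failures.append("network.cutoff_nm must be positive")
    if cfg["ensemble"]["kind"] not in ("planted_path", "planted_partition"):
        failures.append(f"unknown ensemble kind {cfg['ensemble']['kind']!r}")
    windows = cfg["umbrella"]["windows"]
    if any(b <= a for a, b in zip(windows, windows[1:])):
        failures.append("umbrella.windows must be strictly increasing")
    if cfg["umbrella"]["spring_constant_kj_mol_nm2"] <= 0:
        failures.append("umbrella spring constant must be positive")
    stages = cfg["stages"]

    def has_ensemble_source(before: str) -> bool:
        i = stages.index(before)
        return ("synth_ensemble" in stages[:i]
                or (cfg["inputs"]["topology"] and cfg["inputs"]["trajectory"]))

    for stage in ("network", "contacts", "orderparams", "pca"):
        if stage in stages and not has_ensemble_source(stage):
            failures.append(f"stage {stage!r} needs synth_ensemble earlier in the "
                            "stage list or inputs.topology+inputs.trajectory")
    if "paths" in stages:
        if "network" not in stages[:stages.index("paths")]:
            failures.append("stage 'paths' needs stage 'network' before it")
        pc = cfg["paths"]
        src = pc["source"] if pc["source"] is not None else cfg["ensemble"]["source"]
        snk = pc["sink"] if pc["sink"] is not None else cfg["ensemble"]["sink"]
        if src is None or snk is None:
            failures.append("paths stage needs source and sink residues")
        elif src == snk:
            failures.append("paths source and sink must differ")
    if "communities" in stages and "network" not in stages[:stages.index("communities")]:
        failures.append("stage 'communities' needs stage 'network' before it")
    if "wham" in stages:
        i = stages.index("wham")
        if "synth_umbrella" not in stages[:i] and not cfg["inputs"]["umbrella_meta"]:
            failures.append("stage 'wham' needs synth_umbrella earlier or "
                            "inputs.umbrella_meta")
    if not 0 <= cfg["communities"]["min_fraction"] < 1:
        failures.append("communities.min_fraction must lie in [0, 1)")
    return PipelineConfig(cfg, failures)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, cfg: dict, out_dir: str):
        self.cfg = cfg
        self.out = out_dir
        self.topology: Optional[Topology] = None
        self.ensemble: Optional[FrameEnsemble] = None
        self.truth: Optional[syn.GroundTruth] = None
        self.umbrella: Optional[fe.UmbrellaDataset] = None
        self.network: Optional[net.DynamicNetwork] = None
        self.nodes: Optional[net.NodeMap] = None
        self.pathset: Optional[net.PathSet] = None
        self.partition = None
        self.outputs: list[str] = []
        self.warnings: list[str] = []

    def path(self, name: str) -> str:
        p = os.path.join(self.out, name)
        self.outputs.append(p)
        return p

    def resolve_node(self, resid: int) -> int:
        label = self.topology.residue_label(
            int(np.flatnonzero(self.topology.resids == resid)[0]))
        return self.nodes.index_of(label)


def _stage_synth_ensemble(run: _Run) -> None:
    ec = run.cfg["ensemble"]
    seed = run.cfg["seed"]
    if ec["kind"] == "planted_path":
        spec = syn.EnsembleSpec(
            n_residues=ec["n_residues"], n_frames=ec["n_frames"],
            sigma_nm=ec["sigma_nm"], source=ec["source"], sink=ec["sink"],
            n_intermediates=ec["n_intermediates"], rho=ec["rho"],
            background_rho=ec["background_rho"], seed=seed)
        run.topology, run.ensemble, run.truth = syn.make_planted_network_ensemble(spec)
    else:
        spec = syn.PartitionSpec(
            n_residues=ec["n_residues"], n_frames=ec["n_frames"],
            sigma_nm=ec["sigma_nm"], rho_in=ec["rho_in"],
            background_rho=ec["background_rho"], seed=seed)
        run.topology, run.ensemble, run.truth = syn.make_planted_partition_ensemble(spec)
    from .model import write_structure, write_trajectory
    write_structure(run.ensemble, run.path("ensemble.gro"))
    write_trajectory(run.ensemble, run.path("ensemble.xtc"))
    run.truth.to_json(run.path("ground_truth.json"))


def _stage_synth_umbrella(run: _Run) -> None:
    uc = run.cfg["umbrella"]
    spec = syn.UmbrellaSpec(
        potential=uc["potential"], params=uc["params"], windows=uc["windows"],
        spring_constant=uc["spring_constant_kj_mol_nm2"],
        n_samples=uc["n_samples"], temperature=uc["temperature_K"],
        seed=run.cfg["seed"])
    run.umbrella, truth = syn.make_umbrella_dataset(spec)
    meta = fe.write_umbrella_dataset(run.umbrella, run.out)
    run.outputs.append(meta)
    for i in range(len(run.umbrella.windows)):
        run.outputs.append(os.path.join(run.out, f"window_{i:03d}.dat"))
    truth.to_json(run.path("umbrella_ground_truth.json"))


def _require_ensemble(run: _Run) -> None:
    if run.ensemble is None:
        inp = run.cfg["inputs"]
        run.topology, _ = load_structure(inp["topology"])
        run.ensemble = load_trajectory(run.topology, inp["trajectory"],
                                       topology_path=inp["topology"])


def _stage_network(run: _Run) -> None:
    _require_ensemble(run)
    nc = run.cfg["network"]
    run.nodes = net.assign_nodes(run.topology, select(run.topology, "all"))
    run.network = net.build_network(run.ensemble, run.nodes,
                                    cutoff_nm=nc["cutoff_nm"],
                                    persistence=nc["persistence"],
                                    k_neighbours=nc["k_neighbours"])
    run.network.to_tsv(run.path("network_edges.tsv"))
    run.network.to_graphml(run.path("network.graphml"))


def _stage_paths(run: _Run) -> None:
    pc = run.cfg["paths"]
    src = pc["source"] if pc["source"] is not None else run.cfg["ensemble"]["source"]
    snk = pc["sink"] if pc["sink"] is not None else run.cfg["ensemble"]["sink"]
    run.pathset = net.suboptimal_paths(run.network, run.resolve_node(src),
                                       run.resolve_node(snk), pc["n_suboptimal"])
    run.pathset.to_json(run.path("paths.json"), run.nodes.labels)


def _stage_communities(run: _Run) -> None:
    cc = run.cfg["communities"]
    part = net.detect_communities(run.network, seed=cc["seed"],
                                  min_fraction=cc["min_fraction"])
    part = net.community_betweenness(run.network, part)
    run.partition = part
    payload = {
        "seed": part.seed,
        "communities": {str(c): m for c, m in part.communities.items()},
        "discarded": part.discarded,
        "node_betweenness": part.node_betweenness,
        "community_matrix": part.community_matrix.tolist(),
    }
    with open(run.path("communities.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _stage_contacts(run: _Run) -> None:
    _require_ensemble(run)
    table = contacts_mod.contact_frequencies(run.ensemble)
    table.to_tsv(run.path("contacts.tsv"))


def _stage_orderparams(run: _Run) -> None:
    _require_ensemble(run)
    oc = run.cfg["orderparams"]
    if oc["torsion_groups"]:
        groups = [select(run.topology, expr) for expr in oc["torsion_groups"]]
        series = geo.subdomain_torsion(run.ensemble, groups)
        series.to_tsv(run.path("torsion.tsv"), run.ensemble.times)
    for i, dc in enumerate(oc["distances"]):
        series = geo.group_distance(run.ensemble,
                                    select(run.topology, dc["a"]),
                                    select(run.topology, dc["b"]),
                                    mode=dc.get("mode", "com"),
                                    name=dc.get("name", f"distance_{i}"))
        series.to_tsv(run.path(f"{series.name}.tsv"), run.ensemble.times)


def _stage_pca(run: _Run) -> None:
    _require_ensemble(run)
    pc = run.cfg["pca"]
    fit = select(run.topology, pc["fit"])
    fitted, _ = superpose(run.ensemble, fit)
    result = geo.pca(fitted, fit, n_components=pc["n_components"])
    with open(run.path("pca.json"), "w") as fh:
        json.dump({
            "eigenvalues_nm2": result.eigenvalues.tolist(),
            "variance_fractions": result.variance_fractions.tolist(),
        }, fh, indent=1)
    np.savetxt(run.path("pca_projections.tsv"), result.projections,
               delimiter="\t", header="projections", comments="")


def _stage_wham(run: _Run) -> None:
    if run.umbrella is None:
        run.umbrella = fe.load_umbrella_dataset(run.cfg["inputs"]["umbrella_meta"])
    wc = run.cfg["wham"]
    if wc["n_boot"] and wc["n_boot"] > 1:
        profile, _ = fe.bootstrap_error(run.umbrella, n_bins=wc["n_bins"],
                                        n_boot=wc["n_boot"], seed=run.cfg["seed"])
    else:
        profile = fe.wham(run.umbrella, n_bins=wc["n_bins"],
                          tolerance=wc["tolerance_kt"])
    profile.to_tsv(run.path("free_energy_profile.tsv"))
    states = wc.get("states") or {}
    if len(states) >= 2:
        names = sorted(states)
        defs = {n: fe.StateDefinition(n, *states[n]) for n in names}
        results = {}
        for a in names:
            for b in names:
                if a < b:
                    try:
                        dg, err = fe.delta_g(profile, defs[a], defs[b],
                                             run.umbrella.temperature)
                        results[f"{a}->{b}"] = {"delta_g_kcal": dg, "err_kcal": err}
                    except ValueError as exc:
                        results[f"{a}->{b}"] = {"error": str(exc)}
        with open(run.path("delta_g.json"), "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)


def _stage_sensitivity(run: _Run) -> None:
    sc = run.cfg["sensitivity"]
    pc = run.cfg["paths"]
    src = pc["source"] if pc["source"] is not None else run.cfg["ensemble"]["source"]
    snk = pc["sink"] if pc["sink"] is not None else run.cfg["ensemble"]["sink"]
    nc = run.cfg["network"]
    df = net.sensitivity_scan(
        run.ensemble, run.nodes, run.resolve_node(src), run.resolve_node(snk),
        cutoffs_nm=sc["cutoffs_nm"], persistences=sc["persistences"],
        reference=(nc["cutoff_nm"], nc["persistence"]),
        n_suboptimal=pc["n_suboptimal"], k_neighbours=nc["k_neighbours"])
    df.to_csv(run.path("sensitivity.tsv"), sep="\t", index=False)
    with open(run.path("sensitivity_occurrence.json"), "w") as fh:
        json.dump({str(k): v for k, v in df.attrs["node_occurrence"].items()},
                  fh, indent=1, sort_keys=True)


def _stage_report(run: _Run) -> None:
    report: dict = {"stages_run": [s for s in run.cfg["stages"] if s != "report"]}
    if run.pathset is not None and run.truth is not None and run.truth.planted_path:
        found = [int(run.nodes.labels[n].rsplit(":", 1)[1]) for n in run.pathset.optimal]
        report["optimal_path_resids"] = found
        report["planted_path_resids"] = run.truth.planted_path
        report["planted_path_recovered"] = (found == run.truth.planted_path
                                            or found == run.truth.planted_path[::-1])
    if run.partition is not None:
        report["community_sizes"] = run.partition.sizes()
        report["n_discarded_nodes"] = len(run.partition.discarded)
    with open(run.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


_STAGE_FUNCS = {
    "synth_ensemble": _stage_synth_ensemble,
    "synth_umbrella": _stage_synth_umbrella,
    "network": _stage_network,
    "paths": _stage_paths,
    "communities": _stage_communities,
    "contacts": _stage_contacts,
    "orderparams": _stage_orderparams,
    "pca": _stage_pca,
    "wham": _stage_wham,
    "sensitivity": _stage_sensitivity,
    "report": _stage_report,
}


def run(config: Optional[dict], output_dir: Optional[str] = None) -> dict:
    """Validate, execute all stages in order, and write the manifest.

    Returns the manifest dict.  Raises ``ValueError`` before any compute when
    validation fails; a stage failure leaves a partial manifest recording the
    completed stages.
    """
    pc = validate(config)
    if not pc.valid:
        raise ValueError("invalid pipeline config: " + "; ".join(pc.failures))
    cfg = pc.data
    out_dir = output_dir or cfg["output_dir"]
    os.makedirs(out_dir, exist_ok=True)
    state = _Run(cfg, out_dir)
    log_path = os.path.join(out_dir, "run.log")
    timings = []
    completed = []
    failure = None
    import warnings as _warnings
    for stage in cfg["stages"]:
        t0 = time.time()
        try:
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                _STAGE_FUNCS[stage](state)
            state.warnings.extend(f"{stage}: {w.message}" for w in caught)
        except Exception as exc:
            failure = f"{stage}: {exc}"
            break
        timings.append((stage, time.time() - t0))
        completed.append(stage)
    manifest = {
        "config": cfg,
        "version": __version__,
        "stages_completed": completed,
        "outputs": {os.path.relpath(p, out_dir): _sha256(p)
                    for p in state.outputs if os.path.exists(p)},
    }
    if failure:
        manifest["failure"] = failure
    manifest_path = os.path.join(out_dir, "manifest.json")
    tmp = manifest_path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    os.replace(tmp, manifest_path)
    with open(log_path, "w") as fh:
        for stage, dt in timings:
            fh.write(f"{stage}\t{dt:.3f}s\n")
        for w in state.warnings:
            fh.write(f"WARNING\t{w}\n")
        if failure:
            fh.write(f"FAILED\t{failure}\n")
    if failure:
        raise RuntimeError(f"pipeline stage failed: {failure}")
    return manifest
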