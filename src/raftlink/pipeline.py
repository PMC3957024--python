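"""End-to-end orchestration: simulate/load -> quantify -> partitioning shifts
-> co-purification filter -> lipidomics -> lipid-protein network.

A run is fully determined by its RunConfig (including the seed); every
intermediate table is written to the output directory along with a manifest
(parameters, seed, output checksums) and a human-readable summary. Manifests
contain no timestamps so identical runs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import copurify, io, lipidomics, network, quant, ratio_shift, synthetic
from .config import AnalysisParams, ConfigError, MissingnessModel, SimulationConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending inputs."""


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    outdir: str = "raftlink_run"
    skip_lipids: bool = False
    skip_network: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = dict(raw.get("simulation", {}))
        if "missing" in sim_raw and isinstance(sim_raw["missing"], dict):
            sim_raw["missing"] = MissingnessModel(**sim_raw["missing"])
        for key in ("peptides_per_protein", "genotypes", "fractions", "lipid_classes"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
        ana = AnalysisParams(**raw.get("analysis", {}))
        return cls(
            simulation=sim,
            analysis=ana,
            seed=int(raw.get("seed", sim.seed)),
            outdir=str(raw.get("outdir", "raftlink_run")),
            skip_lipids=bool(raw.get("skip_lipids", False)),
            skip_network=bool(raw.get("skip_network", False)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # environment detail, not part of the analysis
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation.replace(seed=config.seed)
    ana = config.analysis
    manifest: dict = {
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "stages": [],
        "summary": {},
        "checksums": {},
    }
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        io.write_table(df, path, index=index)
        written.append(path)

    # -- simulate -----------------------------------------------------------
    evidence, design, truth_p = _stage("simulate")(synthetic.simulate_evidence)(sim)
    annotations = synthetic.simulate_annotations(
        [f"P{i:05d}" for i in range(sim.n_proteins)], seed=config.seed + 17
    )
    io.write_evidence(evidence, outdir / "evidence.tsv")
    written.append(outdir / "evidence.tsv")
    _write(design, "design.tsv")
    _write(annotations, "annotations.tsv")
    manifest["stages"].append("simulate")

    # -- quantify -----------------------------------------------------------
    matrix, design, audit = _stage("quantify")(quant.quantify)(
        evidence, design, ana.min_presence,
        per_genotype=ana.presence_per_genotype,
        require_all_fractions=ana.require_all_fractions,
    )
    if matrix.abundance.empty:
        raise PipelineError("stage 'quantify' failed: no peptides survived filtering")
    _write(matrix.abundance, "protein_matrix.tsv", index=True)
    _write(audit, "peptide_filter_audit.tsv")
    manifest["stages"].append("quantify")
    manifest["summary"]["n_proteins_quantified"] = int(len(matrix.abundance))

    # -- partitioning shifts ------------------------------------------------
    results = _stage("ratio_shift")(ratio_shift.classify_proteins)(
        matrix, design, ana, seed=config.seed + 1
    )
    _write(results, "ratio_shift_results.tsv")
    manifest["stages"].append("ratio_shift")

    # -- co-purification filter --------------------------------------------
    calls = _stage("copurify")(copurify.flag_copurifying)(matrix, design, ana.copurify_alpha)
    retained, excluded = _stage("copurify")(copurify.filter_results)(results, calls)
    _write(calls, "copurify_calls.tsv")
    _write(retained, "ratio_shift_retained.tsv")
    _write(excluded, "ratio_shift_excluded.tsv")
    manifest["stages"].append("copurify")
    sig = retained[retained["significant"]]
    manifest["summary"]["n_significant_retained"] = int(len(sig))
    manifest["summary"]["n_significant_by_direction"] = (
        sig["direction"].value_counts().to_dict()
    )
    manifest["summary"]["n_copurifying_excluded"] = int(len(excluded))

    # -- lipidomics ---------------------------------------------------------
    species_results = None
    if config.skip_lipids:
        manifest["summary"]["lipids"] = "skipped"
    else:
        pos, neg, truth_l = _stage("lipids")(synthetic.simulate_lipids)(sim)
        truth = truth_p.merge(truth_l)
        truth.to_json(outdir / "ground_truth.json")
        written.append(outdir / "ground_truth.json")
        merged = _stage("lipids")(lipidomics.merge_modes)(pos, neg)
        norm = _stage("lipids")(lipidomics.normalize_lipids)(merged)
        trans = _stage("lipids")(lipidomics.transform_lipids)(norm.table)
        ldesign = synthetic.lipid_design(sim)
        diff = _stage("lipids")(lipidomics.differential_lipids)(
            norm.table, trans.table, ldesign, ana.lipid_alpha
        )
        species_results = diff.species
        _write(merged, "lipids_merged.tsv")
        _write(norm.table, "lipids_normalized.tsv")
        _write(diff.species, "lipid_results_species.tsv")
        _write(diff.classes, "lipid_results_classes.tsv")
        manifest["stages"].append("lipids")
        sig_lip = diff.species[diff.species["significant"]]
        manifest["summary"]["n_significant_lipids"] = int(len(sig_lip))
        manifest["summary"]["n_significant_lipids_by_class"] = (
            sig_lip["class"].value_counts().to_dict()
        )
    if not config.skip_lipids:
        manifest["summary"]["ground_truth"] = {
            "n_shifted": len(truth.shifted_proteins),
            "n_copurifying": len(truth.copurifying_proteins),
            "n_differential_lipids": len(truth.differential_lipids),
        }

    # -- network ------------------------------------------------------------
    if not config.skip_network:
        if species_results is None:
            raise PipelineError(
                "stage 'network' failed: lipid results are required but the lipid "
                "stage was skipped (drop skip_lipids or set skip_network)"
            )
        edges = _stage("network")(network.score_edges)(retained, species_results)
        all_scores = results.loc[results["testable"], "score"].to_numpy()
        all_fcs = species_results["log2_fc"].to_numpy()
        fdr_res = _stage("network")(network.permutation_fdr)(
            edges, all_scores, all_fcs,
            fdr=ana.edge_fdr, n_perm=ana.edge_n_perm, seed=config.seed + 2,
        )
        graph = _stage("network")(network.build_graph)(
            fdr_res.edges, annotations, retained, species_results
        )
        degrees = network.degree_table(graph)
        _write(fdr_res.edges, "edges.tsv")
        _write(degrees, "node_degrees.tsv")
        nx.write_graphml(graph, outdir / "network.graphml")
        written.append(outdir / "network.graphml")
        manifest["stages"].append("network")
        manifest["summary"]["n_candidate_edges"] = int(len(fdr_res.edges))
        manifest["summary"]["n_significant_edges"] = int(fdr_res.edges["significant"].sum()) if len(fdr_res.edges) else 0
        manifest["summary"]["n_nodes"] = graph.number_of_nodes()
        lipid_deg = degrees[degrees["kind"] == "lipid"]
        manifest["summary"]["top_degree_lipid"] = (
            str(lipid_deg.iloc[0]["node"]) if len(lipid_deg) else None
        )

    for path in written:
        manifest["checksums"][path.name] = io.sha256_file(path)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_summary(manifest, outdir / "summary.txt")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_summary(manifest: dict, path: Path) -> None:
    lines = ["run summary", "==========="]
    for key, value in sorted(manifest["summary"].items()):
        lines.append(f"{key}: {value}")
    lines.append(f"stages: {', '.join(manifest['stages'])}")
    path.write_text("\n".join(lines) + "\n")
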