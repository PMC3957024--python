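"""Significance-filtered lipid-protein correlation network.

Edge score = lipid log2 fold change x protein partitioning-shift score, for
every significantly shifted protein crossed with every lipid that has a
defined fold change. Edge significance is calibrated against a null score
population built by independently shuffling the two factor vectors and
re-pairing them at random over many rounds; per-tail thresholds are taken at
the configured false-discovery level of that null population.
"""
from __future__ import annotations

import logging
from typing import Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def score_edges(results: pd.DataFrame, lipid_results: pd.DataFrame) -> pd.DataFrame:
    """Candidate edge table: significant proteins x lipids with defined FC."""
    sig = results[results.get("significant", False) & np.isfinite(results["score"])]
    lip = lipid_results[np.isfinite(lipid_results["log2_fc"])]
    if sig.empty:
        logger.warning("no significant proteins; edge table is empty")
        return pd.DataFrame(columns=["protein_id", "lipid_id", "edge_score"])
    prot = sig[["protein_id", "score"]].reset_index(drop=True)
    lipids = lip[["lipid_id", "log2_fc"]].reset_index(drop=True)
    cross = prot.merge(lipids, how="cross")
    cross["edge_score"] = cross["score"] * cross["log2_fc"]
    return cross[["protein_id", "lipid_id", "score", "log2_fc", "edge_score"]]


class EdgeFdrResult(NamedTuple):
    edges: pd.DataFrame          # candidate edges with a `significant` flag
    threshold_lo: float
    threshold_hi: float
    null_scores: np.ndarray


def permutation_fdr(
    edges: pd.DataFrame,
    protein_scores: np.ndarray,
    lipid_fcs: np.ndarray,
    fdr: float = 0.01,
    n_perm: int = 200,
    seed: int = 0,
) -> EdgeFdrResult:
    """Threshold candidate edge scores against a randomized-pairing null.

    Each permutation round independently shuffles the protein-score and
    lipid-FC vectors (without replacement, preserving both marginals exactly)
    and pairs them elementwise; products over all rounds form the null score
    population. Per-tail thresholds are the (1 - fdr/2) upper and fdr/2 lower
    null quantiles; an edge is significant iff its score falls strictly
    beyond a threshold.
    """
    out = edges.copy()
    if out.empty:
        return EdgeFdrResult(out.assign(significant=pd.Series(dtype=bool)),
                             -np.inf, np.inf, np.array([]))
    scores = np.asarray(protein_scores, dtype=float)
    fcs = np.asarray(lipid_fcs, dtype=float)
    scores = scores[np.isfinite(scores)]
    fcs = fcs[np.isfinite(fcs)]
    if scores.size == 0 or fcs.size == 0:
        raise ValueError("need finite protein scores and lipid fold changes")

    rng = np.random.default_rng(seed)
    n = max(scores.size, fcs.size)
    null = np.empty(n_perm * n)
    for r in range(n_perm):
        s = rng.permutation(scores)
        f = rng.permutation(fcs)
        s = np.resize(s, n)
        f = np.resize(f, n)
        null[r * n:(r + 1) * n] = s * f
    if np.all(null == 0):
        logger.warning("degenerate all-zero null; retaining all candidate edges")
        out["significant"] = True
        return EdgeFdrResult(out, -np.inf, np.inf, null)
    hi = float(np.quantile(null, 1.0 - fdr / 2.0, method="higher"))
    lo = float(np.quantile(null, fdr / 2.0, method="lower"))
    out["significant"] = (out["edge_score"] > hi) | (out["edge_score"] < lo)
    return EdgeFdrResult(out, lo, hi, null)


def build_graph(
    edges: pd.DataFrame,
    protein_annotations: pd.DataFrame | None = None,
    results: pd.DataFrame | None = None,
    lipid_results: pd.DataFrame | None = None,
) -> nx.Graph:
    """Bipartite graph of significant edges with annotated nodes.

    Protein nodes carry localization / group / PTM attributes (defaulting to
    "unknown") and the DRM/DSF direction; lipid nodes carry class and FC
    direction. Duplicate (protein, lipid) rows are collapsed with a log entry.
    """
    sig = edges[edges["significant"]] if "significant" in edges.columns else edges
    dup = sig.duplicated(["protein_id", "lipid_id"])
    if dup.any():
        logger.error("collapsing %d duplicate edges", int(dup.sum()))
        sig = sig[~dup]

    g = nx.Graph()
    ann = {}
    if protein_annotations is not None:
        ann = protein_annotations.set_index("protein_id").to_dict("index")
    directions = {}
    if results is not None and "direction" in results.columns:
        directions = dict(zip(results["protein_id"], results["direction"]))
    lipid_meta = {}
    if lipid_results is not None:
        for _, row in lipid_results.iterrows():
            lipid_meta[row["lipid_id"]] = {
                "lipid_class": row.get("class", "unknown"),
                "fc_direction": "up" if row["log2_fc"] > 0 else ("down" if row["log2_fc"] < 0 else "none"),
            }

    for _, row in sig.iterrows():
        pid, lid = row["protein_id"], row["lipid_id"]
        if pid not in g:
            a = ann.get(pid, {})
            g.add_node(
                pid, bipartite="protein",
                localization=str(a.get("localization", "unknown")),
                group=str(a.get("group", "unknown")),
                direction=str(directions.get(pid, "unknown")),
                **{k: bool(a[k]) for k in ("phospho", "palmitoyl", "myristoyl", "gpi_anchor") if k in a},
            )
        if lid not in g:
            meta = lipid_meta.get(lid, {"lipid_class": "unknown", "fc_direction": "unknown"})
            g.add_node(lid, bipartite="lipid", **meta)
        g.add_edge(pid, lid, score=float(row["edge_score"]),
                   sign="positive" if row["edge_score"] >= 0 else "negative")
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return g


class SubnetworkResult(NamedTuple):
    subnetworks: dict[str, dict[str, nx.Graph]]  # mutant -> direction -> graph
    shared_groups: list[str]
    report: pd.DataFrame


def extract_subnetworks(
    graph_a: nx.Graph,
    graph_b: nx.Graph,
    group_map: Mapping[str, str],
    names: tuple[str, str] = ("mutantA", "mutantB"),
) -> SubnetworkResult:
    """Edges restricted to protein groups represented in both mutants' graphs,
    split by DRM/DSF direction.

    Proteins absent from ``group_map`` get singleton groups (logged).
    """
    def _protein_nodes(g: nx.Graph) -> list[str]:
        return [n for n, d in g.nodes(data=True) if d.get("bipartite") == "protein"]

    def _group(pid: str) -> str:
        if pid not in group_map:
            logger.info("protein %s missing from group map; singleton group", pid)
            return f"singleton:{pid}"
        return group_map[pid]

    groups_a = {_group(p) for p in _protein_nodes(graph_a)}
    groups_b = {_group(p) for p in _protein_nodes(graph_b)}
    shared = sorted(groups_a & groups_b)

    subnetworks: dict[str, dict[str, nx.Graph]] = {}
    report_rows = []
    for name, g in zip(names, (graph_a, graph_b)):
        keep = [p for p in _protein_nodes(g) if _group(p) in shared]
        subnetworks[name] = {}
        for direction in ("enriched", "depleted"):
            sel = [p for p in keep if g.nodes[p].get("direction") == direction]
            lipids = {l for p in sel for l in g.neighbors(p)}
            sub = g.subgraph(sel + sorted(lipids)).copy()
            subnetworks[name][direction] = sub
            report_rows.append(
                (name, direction, len(sel), len({_group(p) for p in sel}),
                 sub.number_of_edges())
            )
    report = pd.DataFrame(
        report_rows, columns=["mutant", "direction", "n_proteins", "n_groups", "n_edges"]
    )
    return SubnetworkResult(subnetworks, shared, report)


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        (n, d.get("bipartite", "unknown"), graph.degree[n])
        for n, d in graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["node", "kind", "degree"]).sort_values(
        "degree", ascending=False, ignore_index=True
    )
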