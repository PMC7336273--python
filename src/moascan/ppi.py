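"""Protein-protein interaction network assembly and target-distance annotation.

A high-confidence undirected network is assembled from a STRING-format edge
list (combined score > 900 strictly), simplified (self-loops, duplicate
edges and unconnected nodes removed), and used to annotate every tested
drug-gene association with the unweighted shortest-path distance between the
gene and the drug's nearest nominal target: category "T" when the gene *is*
a target, "1"/"2"/"3" for close network neighbours, "4"/"5+" for remote
ones, and "-" when no target is annotated or no path exists.  A weighted
variant carries the Pearson correlation of the two endpoints' fitness
profiles on every edge and supports per-drug subnetwork extraction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("moascan")

SCORE_THRESHOLD = 900
R2_THRESHOLD = 0.3
DISTANCE_CATEGORIES = ["T", "1", "2", "3", "4", "5+", "-"]


def load_string_network(
    edges: pd.DataFrame | str,
    id_mapping: Mapping[str, Iterable[str] | str] | None = None,
    score_threshold: int = SCORE_THRESHOLD,
) -> nx.Graph:
    """Build the network from a STRING-dialect edge table.

    ``edges`` is a DataFrame or delimited file with columns ``protein1``,
    ``protein2`` and ``combined_score`` (integer 0-999 scale).  Only edges
    with score strictly greater than ``score_threshold`` are kept.
    ``id_mapping`` maps protein identifiers to gene symbols; identifiers with
    no mapping, or with multiple candidate symbols, are removed together with
    their edges.  Malformed rows are counted and logged, not fatal.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "read"):
        edges = pd.read_csv(edges, sep=None, engine="python")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")

    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    malformed = scores.isna() | edges["protein1"].isna() | edges["protein2"].isna()
    if malformed.any():
        logger.warning("load_string_network: %d malformed rows skipped", malformed.sum())
    valid = edges[~malformed]
    scores = scores[~malformed]
    if ((scores < 0) | (scores > 999)).any():
        raise ValueError("combined scores outside the 0-999 STRING scale")
    valid = valid[scores > score_threshold]

    def resolve(protein: str) -> str | None:
        if id_mapping is None:
            return protein
        symbols = id_mapping.get(protein)
        if symbols is None:
            return None
        if isinstance(symbols, str):
            return symbols
        symbols = list(symbols)
        return symbols[0] if len(symbols) == 1 else None

    graph = nx.Graph()
    for p1, p2, score in valid[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        a, b = resolve(p1), resolve(p2)
        if a is None or b is None:
            continue
        graph.add_edge(a, b, combined_score=int(score))
    return graph


def simplify_network(net: nx.Graph) -> nx.Graph:
    """Remove self-loops and unconnected nodes; idempotent.

    Duplicate edges are already collapsed by the undirected graph container.
    """
    out = net.copy()
    out.remove_edges_from(nx.selfloop_edges(out))
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def network_summary(net: nx.Graph) -> dict:
    """Node/edge counts and average shortest-path length over connected pairs."""
    total, pairs = 0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            if target != source:
                total += d
                pairs += 1
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "avg_path_length": total / pairs if pairs else float("nan"),
    }


def _min_target_distances(net: nx.Graph, targets: Iterable[str]) -> dict:
    """Shortest unweighted distance from every reachable node to the nearest target."""
    best: dict = {}
    for t in targets:
        if t not in net:
            continue
        for node, d in nx.single_source_shortest_path_length(net, t).items():
            if node not in best or d < best[node]:
                best[node] = d
    return best


def distance_category(distance: int | None) -> str:
    if distance is None:
        return "-"
    if distance == 0:
        return "T"
    if distance <= 3:
        return str(distance)
    return "4" if distance == 4 else "5+"


def annotate_target_distance(
    results: pd.DataFrame,
    net: nx.Graph,
    drug_targets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Distance annotation for every (drug, gene) row of a results table.

    For drugs with multiple targets the smallest shortest path over all
    targets is taken.  Returns the results with ``ppi_distance`` (integer,
    -1 when undefined) and ``ppi_category`` columns appended; rows whose
    drug has no target annotation get category "-" with reason
    ``no_target_annotation``.
    """
    out = results.copy()
    distances = np.full(len(out), -1, dtype=int)
    categories = np.empty(len(out), dtype=object)
    reasons = np.empty(len(out), dtype=object)
    reasons[:] = ""

    for drug, block in out.groupby("drug_id", sort=False):
        idx = out.index.get_indexer(block.index)
        targets = set(drug_targets.get(drug, ()))
        if not targets:
            categories[idx] = "-"
            reasons[idx] = "no_target_annotation"
            continue
        if not any(t in net for t in targets):
            categories[idx] = "-"
            reasons[idx] = "target_not_in_network"
            continue
        best = _min_target_distances(net, targets)
        for i, gene in zip(idx, block["predictor_id"]):
            if gene in targets:
                distances[i], categories[i] = 0, "T"
            elif gene in best:
                distances[i] = best[gene]
                categories[i] = distance_category(best[gene])
            else:
                categories[i] = "-"
                reasons[i] = "unreachable_or_absent"
    out["ppi_distance"] = distances
    out["ppi_category"] = categories
    out["ppi_reason"] = reasons
    return out


def weight_network(net: nx.Graph, sfm) -> nx.Graph:
    """Weight every edge with the Pearson r of its endpoints' fitness profiles.

    Nodes not covered by the fitness matrix are removed with their edges;
    edges touching a zero-variance profile are dropped with a warning count.
    """
    values = sfm.values if isinstance(getattr(sfm, "values", None), pd.DataFrame) else sfm
    covered = [n for n in net.nodes if n in values.index]
    out: nx.Graph = net.subgraph(covered).copy()

    arr = values.loc[covered].to_numpy(dtype=float)
    sd = arr.std(axis=1)
    z = np.zeros_like(arr)
    ok = sd > 0
    z[ok] = (arr[ok] - arr[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    z_index = {g: i for i, g in enumerate(covered)}
    n = arr.shape[1]

    dropped = 0
    for a, b in list(out.edges):
        ia, ib = z_index[a], z_index[b]
        if not (ok[ia] and ok[ib]):
            out.remove_edge(a, b)
            dropped += 1
            continue
        out[a][b]["weight"] = float(z[ia] @ z[ib] / n)
    if dropped:
        logger.warning("weight_network: dropped %d edges with zero-variance profiles", dropped)
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def drug_subnetwork(
    weighted: nx.Graph,
    drug: str,
    results: pd.DataFrame,
    drug_targets: Mapping[str, Iterable[str]],
    r2_threshold: float = R2_THRESHOLD,
    fdr_threshold: float = 0.10,
) -> nx.Graph:
    """Neighbourhood of a drug's targets with strongly correlated edges only.

    The induced subgraph on the targets and their direct neighbours is
    filtered to edges with squared fitness correlation above
    ``r2_threshold``; nodes significantly associated with the drug
    (``qval < fdr_threshold``) are flagged with ``significant=True``.  A drug
    absent from the results yields an empty graph carrying a reason.
    """
    block = results[results["drug_id"] == drug]
    if block.empty:
        empty = nx.Graph()
        empty.graph["reason"] = "drug_absent_from_results"
        return empty
    targets = [t for t in drug_targets.get(drug, ()) if t in weighted]
    nodes = set(targets)
    for t in targets:
        nodes.update(weighted.neighbors(t))
    sub: nx.Graph = weighted.subgraph(nodes).copy()
    for a, b, data in list(sub.edges(data=True)):
        if data.get("weight", 0.0) ** 2 <= r2_threshold:
            sub.remove_edge(a, b)
    significant = set(block.loc[block["qval"] < fdr_threshold, "predictor_id"])
    for node in sub.nodes:
        sub.nodes[node]["significant"] = node in significant
        sub.nodes[node]["is_target"] = node in targets
    return sub


def tabulate_distance_categories(annotated: pd.DataFrame) -> pd.Series:
    """Count associations per distance category (every row categorized once)."""
    counts = annotated["ppi_category"].value_counts()
    return counts.reindex(DISTANCE_CATEGORIES, fill_value=0)
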