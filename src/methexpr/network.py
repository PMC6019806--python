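"""Hub-gene identification on an imported interaction network.

The significant-gene list is projected onto an edge list exported from a
pathway database; hubs are nodes with unusually high degree in the induced
undirected simple graph.  Nodes present in the network but absent from the
input gene list are *intermediates* (added by the network source); they are
eligible as hubs.
"""

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .methstate import ExpressionLevelFlag, GeneMethSummary, is_majority_hyper
from .summary import SignificantGeneLists
from .types import EdgeList

__all__ = ["HubReport", "build_subnetwork", "identify_hubs", "hub_profile",
           "degree_table"]


@dataclass(frozen=True)
class HubReport:
    gene: str
    degree: int
    is_intermediate: bool
    is_hub: bool


def build_subnetwork(edges: EdgeList, input_genes: Iterable[str]) -> nx.Graph:
    """Undirected simple graph over the edge list plus isolated input genes.

    Every node carries an ``is_intermediate`` attribute: True when the node
    was introduced by the network source rather than listed in
    ``input_genes``.  Input genes with no edges are retained at degree 0.
    """
    input_genes = set(input_genes)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(input_genes))
    for e in edges.edges:
        graph.add_edge(e.node_a, e.node_b,
                       interaction_type=e.interaction_type,
                       high_confidence=e.high_confidence)
    for node in graph.nodes:
        graph.nodes[node]["is_intermediate"] = node not in input_genes
    return graph


def identify_hubs(
    graph: nx.Graph,
    mode: str = "top_k",
    k: int = 8,
    degree_min: int | None = None,
) -> list[HubReport]:
    """Rank nodes by degree and mark hubs.

    ``top_k`` keeps the k highest-degree nodes, including every node tied
    with the k-th degree; ``degree_min`` keeps all nodes with degree >=
    ``degree_min``.  The report covers every node, sorted by (-degree,
    name), so the full degree table is always available.
    """
    if mode not in ("top_k", "degree_min"):
        raise ValidationError(f"unknown hub mode {mode!r}")
    if mode == "top_k":
        if k <= 0:
            raise ValidationError("k must be positive")
        if graph.number_of_nodes() == 0:
            raise ValidationError("top_k mode needs a non-empty graph")
    if mode == "degree_min" and degree_min is None:
        raise ValidationError("degree_min mode needs a degree_min value")

    degrees = dict(graph.degree())
    ordered = sorted(degrees, key=lambda node: (-degrees[node], node))
    if mode == "top_k":
        if len(ordered) <= k:
            hub_set = set(ordered)
        else:
            cutoff = degrees[ordered[k - 1]]
            hub_set = {node for node in ordered if degrees[node] >= cutoff}
    else:
        hub_set = {node for node in ordered if degrees[node] >= degree_min}
    return [
        HubReport(node, degrees[node],
                  bool(graph.nodes[node].get("is_intermediate", False)),
                  node in hub_set)
        for node in ordered
    ]


def degree_table(reports: Sequence[HubReport]) -> pd.DataFrame:
    rows = [
        {"gene": r.gene, "degree": r.degree,
         "is_intermediate": r.is_intermediate, "is_hub": r.is_hub}
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "is_intermediate",
                                       "is_hub"])


def hub_profile(
    hubs: Sequence[HubReport],
    gene_lists: SignificantGeneLists,
    meth_summaries: Mapping[str, GeneMethSummary] | None = None,
    expr_flags: Sequence[ExpressionLevelFlag] | None = None,
) -> pd.DataFrame:
    """Join each hub with its list membership, methylation summary, and
    expression flags — the machine-readable hub characterization.

    Hubs absent from the methylation or expression data get empty fields.
    """
    meth_summaries = meth_summaries or {}
    flags_by_gene: dict[str, list[ExpressionLevelFlag]] = {}
    for fl in expr_flags or []:
        flags_by_gene.setdefault(fl.gene, []).append(fl)

    rows = []
    for hub in hubs:
        if not hub.is_hub:
            continue
        if hub.gene in gene_lists.pos_final:
            membership, direction = "pos_final", "positive"
        elif hub.gene in gene_lists.neg_final:
            membership, direction = "neg_final", "negative"
        elif hub.is_intermediate:
            membership, direction = "intermediate", ""
        else:
            membership, direction = "input_only", ""
        ms = meth_summaries.get(hub.gene)
        gene_flags = flags_by_gene.get(hub.gene, [])
        rows.append({
            "gene": hub.gene,
            "degree": hub.degree,
            "membership": membership,
            "direction": direction,
            "n_hyper": ms.n_hyper if ms else pd.NA,
            "pct_hyper": ms.pct_hyper if ms else pd.NA,
            "n_hypo": ms.n_hypo if ms else pd.NA,
            "pct_hypo": ms.pct_hypo if ms else pd.NA,
            "n_na": ms.n_na if ms else pd.NA,
            "pct_na": ms.pct_na if ms else pd.NA,
            "majority_hyper": is_majority_hyper(ms) if ms else pd.NA,
            "n_probesets_below_housekeeping":
                sum(f.below_housekeeping for f in gene_flags) if gene_flags else pd.NA,
            "n_probesets": len(gene_flags) if gene_flags else pd.NA,
        })
    return pd.DataFrame(rows, columns=[
        "gene", "degree", "membership", "direction", "n_hyper", "pct_hyper",
        "n_hypo", "pct_hypo", "n_na", "pct_na", "majority_hyper",
        "n_probesets_below_housekeeping", "n_probesets",
    ])
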