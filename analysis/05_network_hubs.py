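#!/usr/bin/env python
"""Identify hub genes on an interaction network over the final gene list.

A synthetic pathway-style edge list (planted hubs plus intermediate nodes,
standing in for a database export) is generated over the final genes; the
induced graph's degree table is ranked and the top-8 hubs are profiled
against the gene lists, methylation summaries, and expression flags.
"""

import pandas as pd
from study_config import OUT, SEED

from methexpr import build_subnetwork, generate_edge_list, identify_hubs
from methexpr import io as mio
from methexpr.methstate import meth_summary_from_counts
from methexpr.network import degree_table, hub_profile
from methexpr.summary import SignificantGeneLists


def main() -> None:
    sig = pd.read_csv(OUT / "significant_genes.tsv", sep="\t")
    lists = SignificantGeneLists(**{
        name: set(sig.loc[sig["list"] == name, "gene"])
        for name in ("pos_long", "pos_short", "neg_long", "neg_short",
                     "pos_merged", "neg_merged", "pos_final", "neg_final",
                     "all_final")})

    edges = generate_edge_list(lists.all_final, n_hubs=3,
                               n_intermediate_hubs=2, hub_degree=10,
                               seed=SEED)
    mio.write_edge_list(edges, OUT / "edges_synthetic.tsv")
    graph = build_subnetwork(edges, lists.all_final)
    reports = identify_hubs(graph, "top_k", k=8)

    meth = pd.read_csv(OUT / "gene_meth_summary.tsv", sep="\t")
    meth_summaries = {
        r.gene: meth_summary_from_counts(r.gene, int(r.n_hyper),
                                         int(r.n_hypo), int(r.n_na))
        for r in meth.itertuples(index=False)}
    profile = hub_profile([r for r in reports if r.is_hub], lists,
                          meth_summaries)
    mio.write_results({"hub_degrees": degree_table(reports),
                       "hub_report": profile}, OUT)

    hubs = [r for r in reports if r.is_hub]
    n_int = sum(r.is_intermediate for r in hubs)
    print(f"graph: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges "
          f"({len(edges.intermediate_nodes)} intermediates)")
    print(f"{len(hubs)} hubs (ties included), {n_int} of them intermediates:")
    print(profile[["gene", "degree", "membership", "direction",
                   "majority_hyper"]].to_string(index=False))


if __name__ == "__main__":
    main()
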