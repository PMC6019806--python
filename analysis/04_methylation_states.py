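#!/usr/bin/env python
"""Classify probes of the final genes as hyper-/hypomethylated.

For every probe of every final-list gene, runs the one-sample t-test of
mean M-value against zero, summarizes counts and percentages per gene, and
flags probesets sitting below the housekeeping expression level (8).
"""

import pandas as pd
from study_config import DATA, OUT

from methexpr import flag_low_expression
from methexpr import io as mio
from methexpr.methstate import (call_probe_states, is_majority_hyper,
                                meth_summary_frame, probe_states_frame,
                                summarize_gene_meth)


def main() -> None:
    meth = mio.read_matrix(DATA / "methylation.tsv")
    expr = mio.read_matrix(DATA / "expression.tsv")
    annotations = mio.read_annotation(DATA / "annotation.tsv")
    sig = pd.read_csv(OUT / "significant_genes.tsv", sep="\t")
    final_genes = sorted(sig.loc[sig["list"] == "all_final", "gene"])

    states = call_probe_states(meth, annotations, final_genes)
    by_gene: dict[str, list] = {}
    for s in states:
        by_gene.setdefault(s.gene, []).append(s)
    summaries = [summarize_gene_meth(sts) for _, sts in sorted(by_gene.items())]
    flags = flag_low_expression(expr, final_genes, annotations)
    summary_frame = meth_summary_frame(summaries)
    mio.write_results(
        {"probe_states": probe_states_frame(states),
         "gene_meth_summary": summary_frame,
         "expression_flags": pd.DataFrame(
             [{"gene": f.gene, "probeset_id": f.probeset_id,
               "max_expr": f.max_expr,
               "below_housekeeping": f.below_housekeeping} for f in flags])},
        OUT)

    n_major = sum(is_majority_hyper(s) for s in summaries)
    n_low = sum(f.below_housekeeping for f in flags)
    print(f"tested {len(states)} probes across {len(summaries)} final genes")
    print(f"  {n_major} genes majority-hypermethylated; "
          f"{n_low}/{len(flags)} probesets below housekeeping level 8")
    print("first rows of the per-gene state table:")
    print(summary_frame.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
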