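#!/usr/bin/env python
"""Aggregate pair fits into gene-level calls and the final gene lists.

Classifies genes as long/short, applies the 15%/30% significant-pair
thresholds and the majority-direction rule, intersects the resulting
merged lists with the |coefficient| > 0.5 gene sets, and scores the calls
against the simulation ground truth.
"""

import pandas as pd
from study_config import DATA, OUT

from methexpr import io as mio
from methexpr import truth_confusion
from methexpr.model import pair_fits_from_frame
from methexpr.summary import (build_lists, gene_lists_frame,
                              gene_summary_frame, summarize_all_genes)


def main() -> None:
    # keep_default_na=False: "null" is a direction label, not a missing value
    fits = pair_fits_from_frame(
        pd.read_csv(OUT / "pair_fits.tsv", sep="\t",
                    keep_default_na=False, na_values=["NA", ""]))
    annotations = mio.read_annotation(DATA / "annotation.tsv")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t",
                        keep_default_na=False, na_values=["NA", ""])

    summaries = summarize_all_genes(fits, annotations)
    lists = build_lists(summaries, fits)
    analyzable = truth[truth["gene"].isin({s.gene for s in summaries})]
    confusion = truth_confusion(summaries, analyzable)
    mio.write_results(
        {"gene_summary": gene_summary_frame(summaries),
         "significant_genes": gene_lists_frame(lists),
         "confusion": confusion.reset_index()},
        OUT)

    n_long = sum(s.length_class == "long" for s in summaries)
    print(f"summarized {len(summaries)} genes ({n_long} long)")
    print(f"significant long/short lists: "
          f"+{len(lists.pos_long)}/+{len(lists.pos_short)}  "
          f"-{len(lists.neg_long)}/-{len(lists.neg_short)}")
    print(f"merged: {len(lists.pos_merged)} positive, "
          f"{len(lists.neg_merged)} negative")
    print(f"final (merged AND |coeff| > 0.5): {len(lists.pos_final)} positive, "
          f"{len(lists.neg_final)} negative, union {len(lists.all_final)}")
    print("confusion (true x called):")
    print(confusion.to_string())


if __name__ == "__main__":
    main()
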