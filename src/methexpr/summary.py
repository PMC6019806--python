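"""Gene-level aggregation of pair fits: length classes, significance rules,
coefficient filters, and final gene lists.

A gene with m probesets and n probes is *long* when m > 2 or n > 20, else
*short*.  Within each class, a gene is significant when strictly more than
15% (long) or 30% (short) of its non-degenerate pairs reach beta1_p < alpha.
Direction is a majority vote over the sign of beta1 across all
non-degenerate pairs; exactly half is "none", and beta1 == 0 counts for
neither side.  Large-effect lists keep pairs with |beta1| above a cut and
beta1_p < alpha, and the final gene lists intersect the large-effect gene
sets with the merged significant long+short lists, separately by sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .model import PairFit
from .types import GeneAnnotation

__all__ = [
    "GeneSummary", "CoeffFilterResult", "SignificantGeneLists",
    "classify_gene_length", "summarize_gene", "summarize_all_genes",
    "coeff_filter", "merge_long_short", "intersect_final", "build_lists",
    "gene_summary_frame",
]


@dataclass
class GeneSummary:
    gene: str
    length_class: str              # "long" | "short"
    n_pairs: int                   # non-degenerate pairs
    n_sig_pairs: int               # beta1_p < alpha among those
    frac_sig: float
    n_pos_coeff: int
    n_neg_coeff: int
    direction: str                 # "positive" | "negative" | "none"
    passes_frac_threshold: bool
    n_degenerate: int = 0


@dataclass(frozen=True)
class CoeffFilterResult:
    threshold_label: str           # e.g. "gt0.5", "ltm1"
    n_pairs: int
    genes: frozenset[str]


@dataclass
class SignificantGeneLists:
    """The nine gene sets of the list pipeline: per-class significant
    lists, their merges, and the final coefficient-filtered lists."""

    pos_long: set[str] = field(default_factory=set)
    pos_short: set[str] = field(default_factory=set)
    neg_long: set[str] = field(default_factory=set)
    neg_short: set[str] = field(default_factory=set)
    pos_merged: set[str] = field(default_factory=set)
    neg_merged: set[str] = field(default_factory=set)
    pos_final: set[str] = field(default_factory=set)
    neg_final: set[str] = field(default_factory=set)
    all_final: set[str] = field(default_factory=set)


def classify_gene_length(m: int, n: int, probeset_cut: int = 2,
                         probe_cut: int = 20) -> str:
    """"long" iff m > probeset_cut or n > probe_cut (strict), else "short"."""
    if m < 1 or n < 1:
        raise ValidationError("m and n must be >= 1")
    return "long" if (m > probeset_cut or n > probe_cut) else "short"


def summarize_gene(
    fits: Sequence[PairFit],
    m: int,
    n: int,
    alpha: float = 0.05,
    long_frac: float = 0.15,
    short_frac: float = 0.30,
    probeset_cut: int = 2,
    probe_cut: int = 20,
) -> GeneSummary:
    """Aggregate one gene's pair fits into its summary row.

    Counts run over non-degenerate fits only; degenerate fits are tallied
    separately so the dilution they would cause is auditable.  All threshold
    comparisons are strict.
    """
    if not fits:
        raise ValidationError("summarize_gene needs at least one fit")
    genes = {f.gene for f in fits}
    if len(genes) != 1:
        raise ValidationError(f"fits span multiple genes: {sorted(genes)}")
    gene = fits[0].gene
    length_class = classify_gene_length(m, n, probeset_cut, probe_cut)
    ok = [f for f in fits if f.status == "ok"]
    n_pairs = len(ok)
    n_sig = sum(1 for f in ok if f.beta1_p < alpha)
    n_pos = sum(1 for f in ok if f.beta1 > 0)
    n_neg = sum(1 for f in ok if f.beta1 < 0)
    frac = n_sig / n_pairs if n_pairs else 0.0
    if n_pos > n_pairs / 2:
        direction = "positive"
    elif n_neg > n_pairs / 2:
        direction = "negative"
    else:
        direction = "none"
    cutoff = long_frac if length_class == "long" else short_frac
    return GeneSummary(
        gene=gene, length_class=length_class, n_pairs=n_pairs,
        n_sig_pairs=n_sig, frac_sig=frac, n_pos_coeff=n_pos,
        n_neg_coeff=n_neg, direction=direction,
        passes_frac_threshold=bool(n_pairs and frac > cutoff),
        n_degenerate=len(fits) - n_pairs,
    )


def summarize_all_genes(
    fits: Iterable[PairFit],
    annotations: Sequence[GeneAnnotation],
    alpha: float = 0.05,
    long_frac: float = 0.15,
    short_frac: float = 0.30,
    probeset_cut: int = 2,
    probe_cut: int = 20,
) -> list[GeneSummary]:
    """Per-gene summaries for every gene that produced at least one fit."""
    by_gene: dict[str, list[PairFit]] = {}
    for f in fits:
        by_gene.setdefault(f.gene, []).append(f)
    ann_map = {a.gene: a for a in annotations}
    missing = set(by_gene) - set(ann_map)
    if missing:
        raise ValidationError(f"fits for unannotated genes: {sorted(missing)[:5]}")
    return [
        summarize_gene(by_gene[g], ann_map[g].m, ann_map[g].n, alpha,
                       long_frac, short_frac, probeset_cut, probe_cut)
        for g in sorted(by_gene)
    ]


def coeff_filter(
    fits: Iterable[PairFit],
    coeff_cut: float,
    sign: str,
    alpha: float = 0.05,
) -> CoeffFilterResult:
    """Pairs (and their unique genes) with a large, significant methylation coefficient.

    ``sign="pos"`` keeps pairs with beta1 > coeff_cut, ``sign="neg"`` pairs
    with beta1 < -coeff_cut; both additionally require beta1_p < alpha.
    """
    if sign not in ("pos", "neg"):
        raise ValidationError(f"sign must be 'pos' or 'neg', got {sign!r}")
    label = ("gt" if sign == "pos" else "ltm") + f"{coeff_cut:g}"
    hits = [
        f for f in fits
        if f.status == "ok" and f.beta1_p < alpha
        and (f.beta1 > coeff_cut if sign == "pos" else f.beta1 < -coeff_cut)
    ]
    return CoeffFilterResult(label, len(hits), frozenset(f.gene for f in hits))


def merge_long_short(long_set: set[str], short_set: set[str]) -> set[str]:
    """Union of the long and short significant lists; overlap is a contract error."""
    overlap = set(long_set) & set(short_set)
    if overlap:
        raise ValidationError(
            f"genes in both long and short lists (length classes must partition): "
            f"{sorted(overlap)[:5]}"
        )
    return set(long_set) | set(short_set)


def intersect_final(coeff_genes: set[str], summary_genes: set[str]) -> set[str]:
    """Genes present in both a large-coefficient list and a merged significant list."""
    return set(coeff_genes) & set(summary_genes)


def build_lists(
    summaries: Sequence[GeneSummary],
    fits: Sequence[PairFit],
    alpha: float = 0.05,
    coeff_cut_final: float = 0.5,
) -> SignificantGeneLists:
    """Assemble the full gene-list pipeline from summaries and pair fits.

    Long/short significant lists come from the fraction thresholds and the
    majority direction; the final lists intersect them with the
    ``|beta1| > coeff_cut_final`` large-effect gene sets.
    """
    sum_genes = {s.gene for s in summaries}
    fit_genes = {f.gene for f in fits}
    if sum_genes != fit_genes:
        raise ValidationError("summaries and fits cover different gene sets")

    lists = SignificantGeneLists()
    for s in summaries:
        if not s.passes_frac_threshold or s.direction == "none":
            continue
        target = {
            ("positive", "long"): "pos_long", ("positive", "short"): "pos_short",
            ("negative", "long"): "neg_long", ("negative", "short"): "neg_short",
        }[(s.direction, s.length_class)]
        getattr(lists, target).add(s.gene)

    lists.pos_merged = merge_long_short(lists.pos_long, lists.pos_short)
    lists.neg_merged = merge_long_short(lists.neg_long, lists.neg_short)
    pos_coeff = coeff_filter(fits, coeff_cut_final, "pos", alpha)
    neg_coeff = coeff_filter(fits, coeff_cut_final, "neg", alpha)
    lists.pos_final = intersect_final(set(pos_coeff.genes), lists.pos_merged)
    lists.neg_final = intersect_final(set(neg_coeff.genes), lists.neg_merged)
    lists.all_final = lists.pos_final | lists.neg_final
    return lists


def coeff_filter_table(
    fits: Sequence[PairFit],
    coeff_cuts: Sequence[float] = (0.5, 1.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Large-coefficient audit table: pair and unique-gene counts per cut and sign."""
    rows = []
    for cut in coeff_cuts:
        for sign in ("pos", "neg"):
            res = coeff_filter(fits, cut, sign, alpha)
            rows.append({"threshold": res.threshold_label,
                         "n_pairs": res.n_pairs, "n_genes": len(res.genes)})
    return pd.DataFrame(rows, columns=["threshold", "n_pairs", "n_genes"])


def gene_summary_frame(summaries: Iterable[GeneSummary]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene, "length_class": s.length_class, "n_pairs": s.n_pairs,
            "n_sig_pairs": s.n_sig_pairs, "frac_sig": s.frac_sig,
            "n_pos_coeff": s.n_pos_coeff, "n_neg_coeff": s.n_neg_coeff,
            "direction": s.direction,
            "passes_frac_threshold": s.passes_frac_threshold,
            "n_degenerate": s.n_degenerate,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["gene", "length_class", "n_pairs", "n_sig_pairs",
                       "frac_sig", "n_pos_coeff", "n_neg_coeff", "direction",
                       "passes_frac_threshold", "n_degenerate"],
    )


def gene_lists_frame(lists: SignificantGeneLists) -> pd.DataFrame:
    """Long-format membership table of the nine gene sets."""
    rows = []
    for name in ("pos_long", "pos_short", "neg_long", "neg_short", "pos_merged",
                 "neg_merged", "pos_final", "neg_final", "all_final"):
        rows.extend({"list": name, "gene": g} for g in sorted(getattr(lists, name)))
    return pd.DataFrame(rows, columns=["list", "gene"])
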