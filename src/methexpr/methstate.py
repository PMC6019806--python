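"""Hyper-/hypomethylation calls per probe and per-gene summaries.

Each probe's M-values across samples are tested against zero with a
two-sided one-sample t-test.  A probe is *hypermethylated* when its mean
M-value is above 0 with p < alpha, *hypomethylated* when below 0 with
p < alpha, and N/A otherwise (including degenerate probes: fewer than two
values or zero variance).  Gene summaries report counts and percentages by
state; the percentages round half-up to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .types import GeneAnnotation, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMethState", "GeneMethSummary", "ExpressionLevelFlag",
    "probe_t_test", "call_probe_states", "summarize_gene_meth",
    "meth_summary_from_counts", "is_majority_hyper", "flag_low_expression",
]


@dataclass(frozen=True)
class ProbeMethState:
    probe_id: str
    gene: str
    mean_meth: float
    t_stat: float          # NaN when degenerate
    p: float               # NaN when degenerate
    state: str             # "hyper" | "hypo" | "NA"
    degenerate: bool = False


@dataclass(frozen=True)
class GeneMethSummary:
    gene: str
    n_hyper: int
    n_hypo: int
    n_na: int
    pct_hyper: float
    pct_hypo: float
    pct_na: float

    @property
    def n_total(self) -> int:
        return self.n_hyper + self.n_hypo + self.n_na


@dataclass(frozen=True)
class ExpressionLevelFlag:
    gene: str
    probeset_id: str
    max_expr: float
    below_housekeeping: bool


def probe_t_test(
    m_values: Sequence[float] | pd.Series,
    alpha: float = 0.05,
    probe_id: str = "",
    gene: str = "",
) -> ProbeMethState:
    """Classify one probe from its M-values across samples.

    Two-sided one-sample t-test of mean zero; the sign of the mean supplies
    the direction.  Fewer than two non-missing values, or zero variance,
    yields a degenerate N/A call with the test statistics unset.
    """
    vals = pd.Series(m_values, dtype=float).dropna().to_numpy()
    if len(vals) < 2 or np.ptp(vals) == 0.0:
        logger.debug("probe %s: degenerate (%d values)", probe_id, len(vals))
        mean = float(vals.mean()) if len(vals) else float("nan")
        return ProbeMethState(probe_id, gene, mean, float("nan"), float("nan"),
                              "NA", degenerate=True)
    res = scipy.stats.ttest_1samp(vals, popmean=0.0)
    mean = float(vals.mean())
    p = float(res.pvalue)
    if mean > 0 and p < alpha:
        state = "hyper"
    elif mean < 0 and p < alpha:
        state = "hypo"
    else:
        state = "NA"
    return ProbeMethState(probe_id, gene, mean, float(res.statistic), p, state)


def call_probe_states(
    meth: OmicsMatrix,
    annotations: Sequence[GeneAnnotation],
    genes: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[ProbeMethState]:
    """Probe states for every probe of the selected genes (all genes if None)."""
    wanted = set(genes) if genes is not None else {a.gene for a in annotations}
    states = []
    for ann in sorted(annotations, key=lambda a: a.gene):
        if ann.gene not in wanted:
            continue
        for probe in sorted(ann.probes):
            states.append(probe_t_test(meth.feature(probe), alpha,
                                       probe_id=probe, gene=ann.gene))
    return states


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (table-rendering convention)."""
    frac = Decimal(count * 100) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def meth_summary_from_counts(gene: str, n_hyper: int, n_hypo: int,
                             n_na: int) -> GeneMethSummary:
    """Build a gene summary directly from per-state probe counts."""
    total = n_hyper + n_hypo + n_na
    if total < 1:
        raise ValidationError(f"gene {gene}: no probes to summarize")
    return GeneMethSummary(
        gene=gene, n_hyper=n_hyper, n_hypo=n_hypo, n_na=n_na,
        pct_hyper=_pct(n_hyper, total), pct_hypo=_pct(n_hypo, total),
        pct_na=_pct(n_na, total),
    )


def summarize_gene_meth(states: Sequence[ProbeMethState]) -> GeneMethSummary:
    """Count one gene's probes by state and attach rounded percentages."""
    if not states:
        raise ValidationError("summarize_gene_meth needs at least one probe state")
    genes = {s.gene for s in states}
    if len(genes) != 1:
        raise ValidationError(f"probe states span multiple genes: {sorted(genes)}")
    counts = {"hyper": 0, "hypo": 0, "NA": 0}
    for s in states:
        counts[s.state] += 1
    return meth_summary_from_counts(genes.pop(), counts["hyper"],
                                    counts["hypo"], counts["NA"])


def is_majority_hyper(summary: GeneMethSummary) -> bool:
    """True when hypermethylated probes outnumber hypo and N/A probes combined."""
    return summary.n_hyper > summary.n_hypo + summary.n_na


def flag_low_expression(
    expr: OmicsMatrix,
    genes: Iterable[str],
    annotations: Sequence[GeneAnnotation],
    housekeeping_threshold: float = 8.0,
) -> list[ExpressionLevelFlag]:
    """Flag probesets whose maximum expression sits strictly below the
    housekeeping reference level (default 8 on the log2 scale)."""
    ann_map = {a.gene: a for a in annotations}
    flags = []
    for gene in sorted(set(genes)):
        ann = ann_map.get(gene)
        if ann is None or not ann.probesets:
            logger.warning("gene %s: no probesets annotated; skipped", gene)
            continue
        for ps in sorted(ann.probesets):
            mx = float(expr.feature(ps).max())
            flags.append(ExpressionLevelFlag(gene, ps, mx,
                                             mx < housekeeping_threshold))
    return flags


def probe_states_frame(states: Iterable[ProbeMethState]) -> pd.DataFrame:
    rows = [
        {"gene": s.gene, "probe_id": s.probe_id, "mean_meth": s.mean_meth,
         "t_stat": s.t_stat, "p": s.p, "state": s.state,
         "degenerate": s.degenerate}
        for s in states
    ]
    return pd.DataFrame(rows, columns=["gene", "probe_id", "mean_meth",
                                       "t_stat", "p", "state", "degenerate"])


def meth_summary_frame(summaries: Iterable[GeneMethSummary]) -> pd.DataFrame:
    rows = [
        {"gene": s.gene, "n_hyper": s.n_hyper, "pct_hyper": s.pct_hyper,
         "n_hypo": s.n_hypo, "pct_hypo": s.pct_hypo,
         "n_na": s.n_na, "pct_na": s.pct_na,
         "majority_hyper": is_majority_hyper(s)}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["gene", "n_hyper", "pct_hyper", "n_hypo",
                                       "pct_hypo", "n_na", "pct_na",
                                       "majority_hyper"])
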