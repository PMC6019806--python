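"""Synthetic matched expression/methylation datasets with known ground truth.

The generator emulates the shape of a 40-cell-line microarray study: an
RMA-style log-expression matrix (values in [2, 13.5]), a two-color M-value
methylation matrix (values mostly in [-4, 4]), a binary ER status, a
three-level tumor subtype, and a gene annotation mapping each gene to m
expression probesets and n methylation probes.

Generative model, per gene g with true methylation effect beta1_g:

* each probe p carries ``x[p, s] = mu_g + e[p, s]`` where ``mu_g`` is a
  gene-level mean M-value and the probe residuals have standard deviation
  ``meth_sd`` and optional equicorrelation ``rho`` across the gene's probes;
* each probeset k responds to the per-sample across-probe mean
  ``xbar[s]``:  ``y[k, s] = beta0_k + beta1_g * xbar[s] + beta2 * ER[s]
  + beta3[subtype[s]] + N(0, sigma^2)``, then clipped to [2, 13.5].

Because expression couples to the probe *mean*, a single-probe regression
estimates ``beta1_g * (rho + (1 - rho) / n)``: with several independent
probes per gene only a subset of a gene's m x n pairs reaches significance,
mirroring real probe-level heterogeneity.  The default configuration uses
one probeset and one probe per gene, where the fitted pairwise model matches
the generative model exactly and beta1 is identifiable; multi-probe shapes
are requested through ``m_range`` / ``n_range``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    SUBTYPE_LEVELS,
    Edge,
    EdgeList,
    GeneAnnotation,
    OmicsMatrix,
    PhenotypeTable,
)

EXPR_RANGE = (2.0, 13.5)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_edge_list",
    "truth_confusion",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe the identifiable one-probeset x one-probe
    configuration: 40 samples, 100 genes of which 30% carry a positive and
    30% a negative true methylation effect of magnitude 1 on the log2
    expression scale, residual noise sigma = 1.
    """

    n_samples: int = 40
    n_genes: int = 100
    m_range: tuple[int, int] = (1, 1)      # probesets per gene (inclusive)
    n_range: tuple[int, int] = (1, 1)      # probes per gene (inclusive)
    frac_positive: float = 0.3
    frac_negative: float = 0.3
    beta1_magnitude: float = 1.0           # |beta1| for non-null genes
    beta0_range: tuple[float, float] = (7.0, 8.0)    # baseline log2 expression
    beta2: float = 1.0                     # ER+ effect on expression
    beta3_vec: tuple[float, float] = (0.5, -0.5)     # BasalA, BasalB vs Luminal
    sigma: float = 1.0                     # residual SD of expression
    meth_mu_range: tuple[float, float] = (-0.5, 0.5)  # per-gene mean M-value
    meth_sd: float = 1.5                   # probe-level M-value SD
    rho: float = 0.0                       # inter-probe equicorrelation
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 6:
            raise ValidationError("n_samples must be >= 6 to fit the model")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        for name, (lo, hi) in (("m_range", self.m_range), ("n_range", self.n_range)):
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} must be a well-ordered interval >= 1")
        if not (0.0 <= self.frac_positive and 0.0 <= self.frac_negative
                and self.frac_positive + self.frac_negative <= 1.0):
            raise ValidationError("frac_positive + frac_negative must lie in [0, 1]")
        if self.sigma <= 0 or self.meth_sd <= 0:
            raise ValidationError("sigma and meth_sd must be positive")
        for name, (lo, hi) in (("beta0_range", self.beta0_range),
                               ("meth_mu_range", self.meth_mu_range)):
            if hi < lo:
                raise ValidationError(f"{name} is not well ordered")
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("rho must lie in (-1, 1)")
        max_n = self.n_range[1]
        if max_n > 1 and self.rho < -1.0 / (max_n - 1):
            raise ValidationError(
                f"rho={self.rho} is not a valid equicorrelation for n={max_n} probes "
                f"(requires rho >= {-1.0 / (max_n - 1):.3f})"
            )


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    expression: OmicsMatrix
    methylation: OmicsMatrix
    phenotypes: PhenotypeTable
    annotations: list[GeneAnnotation]
    truth: pd.DataFrame  # columns: gene, true_direction, true_beta1, m, n
    n_clipped: int = 0   # expression values clipped into [2, 13.5]

    def __iter__(self):
        yield from (self.expression, self.methylation, self.phenotypes,
                    self.annotations, self.truth)


def _probe_noise(rng: np.random.Generator, n_probes: int, n_samples: int,
                 sd: float, rho: float) -> np.ndarray:
    """Equicorrelated Gaussian probe residuals, (n_probes, n_samples)."""
    if n_probes == 1 or rho == 0.0:
        return sd * rng.standard_normal((n_probes, n_samples))
    if rho > 0.0:
        shared = rng.standard_normal(n_samples)
        own = rng.standard_normal((n_probes, n_samples))
        return sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
    # negative equicorrelation: fall back to an explicit covariance factor
    cov = np.full((n_probes, n_probes), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return sd * (chol @ rng.standard_normal((n_probes, n_samples)))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic study, fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    er = np.where(rng.random(config.n_samples) < 0.5, "ERpos", "ERneg")
    subtype = rng.choice(list(SUBTYPE_LEVELS), size=config.n_samples)
    pheno = PhenotypeTable(pd.DataFrame(
        {"er_status": er, "subtype": subtype},
        index=pd.Index(samples, name="sample_id"),
    ))
    er_ind = (er == "ERpos").astype(float)
    basal_a = (subtype == "BasalA").astype(float)
    basal_b = (subtype == "BasalB").astype(float)
    beta3_a, beta3_b = config.beta3_vec

    n_pos = int(round(config.frac_positive * config.n_genes))
    n_neg = int(round(config.frac_negative * config.n_genes))
    directions = np.array(
        ["positive"] * n_pos + ["negative"] * n_neg
        + ["null"] * (config.n_genes - n_pos - n_neg)
    )
    rng.shuffle(directions)

    width = max(3, len(str(config.n_genes)))
    annotations: list[GeneAnnotation] = []
    truth_rows = []
    expr_rows: dict[str, np.ndarray] = {}
    meth_rows: dict[str, np.ndarray] = {}
    n_clipped = 0

    for g in range(config.n_genes):
        gene = f"G{g + 1:0{width}d}"
        direction = directions[g]
        beta1 = {"positive": config.beta1_magnitude,
                 "negative": -config.beta1_magnitude,
                 "null": 0.0}[direction]
        m = int(rng.integers(config.m_range[0], config.m_range[1] + 1))
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        mu = rng.uniform(*config.meth_mu_range)

        x = mu + _probe_noise(rng, n, config.n_samples, config.meth_sd, config.rho)
        xbar = x.mean(axis=0)
        probes = tuple(f"{gene}_pr{j + 1:03d}" for j in range(n))
        for pid, row in zip(probes, x):
            meth_rows[pid] = row

        probesets = tuple(f"{gene}_ps{k + 1}" for k in range(m))
        for pid in probesets:
            beta0 = rng.uniform(*config.beta0_range)
            y = (beta0 + beta1 * xbar + config.beta2 * er_ind
                 + beta3_a * basal_a + beta3_b * basal_b
                 + config.sigma * rng.standard_normal(config.n_samples))
            clipped = np.clip(y, *EXPR_RANGE)
            n_clipped += int(np.sum(clipped != y))
            expr_rows[pid] = clipped

        annotations.append(GeneAnnotation(gene, probesets, probes))
        truth_rows.append((gene, direction, beta1, m, n))

    expression = OmicsMatrix(pd.DataFrame.from_dict(
        expr_rows, orient="index", columns=samples).rename_axis("feature_id"))
    methylation = OmicsMatrix(pd.DataFrame.from_dict(
        meth_rows, orient="index", columns=samples).rename_axis("feature_id"))
    truth = pd.DataFrame(truth_rows,
                         columns=["gene", "true_direction", "true_beta1", "m", "n"])
    return SyntheticDataset(expression, methylation, pheno, annotations,
                            truth, n_clipped)


def truth_confusion(summaries, truth: pd.DataFrame) -> pd.DataFrame:
    """3x3 confusion matrix of true vs called gene direction.

    ``summaries`` is an iterable of GeneSummary; a gene is *called*
    positive/negative when its majority direction is such and it passes its
    length class's significant-fraction threshold, otherwise null.  Rows are
    the true direction, columns the call, both over
    {positive, negative, null}.
    """
    called = {}
    for s in summaries:
        if s.passes_frac_threshold and s.direction in ("positive", "negative"):
            called[s.gene] = s.direction
        else:
            called[s.gene] = "null"
    truth_map = dict(zip(truth["gene"], truth["true_direction"]))
    if set(called) != set(truth_map):
        missing = set(truth_map) ^ set(called)
        raise ValidationError(f"gene sets differ between summaries and truth: {sorted(missing)[:5]}")
    levels = ["positive", "negative", "null"]
    table = pd.DataFrame(0, index=levels, columns=levels)
    table.index.name = "true"
    table.columns.name = "called"
    for gene, call in called.items():
        table.loc[truth_map[gene], call] += 1
    return table


def generate_edge_list(
    genes,
    n_hubs: int = 3,
    n_intermediate_hubs: int = 2,
    hub_degree: int = 12,
    n_background_edges: int = 15,
    seed: int = 0,
) -> EdgeList:
    """Synthetic interaction network over a gene list, with planted hubs.

    Emulates a pathway-database export for testing the hub analysis:
    ``n_hubs`` genes from the input list and ``n_intermediate_hubs``
    intermediate nodes (nodes the database adds beyond the input list) are
    each wired to ``hub_degree`` randomly chosen input genes; a sparse
    background of random gene-gene edges is added on top.  All edges are
    high-confidence binary protein interactions.
    """
    genes = sorted(set(genes))
    if len(genes) < max(n_hubs, 2):
        raise ValidationError("need at least max(n_hubs, 2) input genes")
    rng = np.random.default_rng(seed)
    hubs = list(rng.choice(genes, size=n_hubs, replace=False))
    intermediates = {f"INT{i + 1}" for i in range(n_intermediate_hubs)}
    edges: set[Edge] = set()
    for hub in list(hubs) + sorted(intermediates):
        degree = min(hub_degree, len(genes) - 1)
        partners = rng.choice([g for g in genes if g != hub],
                              size=degree, replace=False)
        edges.update(Edge(hub, p, "binary_protein", True) for p in partners)
    for _ in range(n_background_edges):
        a, b = rng.choice(genes, size=2, replace=False)
        edges.add(Edge(a, b, "binary_protein", True))
    return EdgeList(edges=edges, intermediate_nodes=intermediates)
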