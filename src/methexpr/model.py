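"""Pairwise linear models of expression on methylation with covariate adjustment.

For every gene, every (expression probeset, methylation probe) pair is fit
with ordinary least squares:

    y_i = beta0 + beta1 * x_i + beta2 * ER_i + beta3[subtype_i] + eps_i

where ``y`` is the probeset's log2 expression, ``x`` the probe's M-value,
and ER status / tumor subtype enter as treatment-coded indicators
(references ERneg and Luminal).  The quantity of interest is beta1, the
methylation coefficient, tested against zero.  By default the test is the
marginal (partial) t-test from the full model, so it is adjusted for ER and
subtype; a sequential (Type I) ANOVA with term order (methylation, ER,
subtype) is available via ``anova="sequential"``.

Probesets whose expression values fail a Shapiro-Wilk normality screen are
excluded from pair enumeration before any fitting, reflecting the linear
model's normality assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import GeneAnnotation, OmicsMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

#: Relative tolerance below which a fit's residual sum of squares counts as zero.
_SSR_REL_TOL = 1e-10

__all__ = ["PairFit", "NormalityReport", "fit_pair", "shapiro_filter",
           "fit_all_pairs", "pair_fits_frame", "pair_fits_from_frame"]


@dataclass
class PairFit:
    """One probeset-probe model fit."""

    gene: str
    probeset_id: str
    probe_id: str
    beta0: float = np.nan
    beta1: float = np.nan
    beta2: float = np.nan            # ER+ effect; NaN when the level was dropped
    beta3_levels: dict = None        # subtype-level effects actually estimated
    beta1_se: float = np.nan
    beta1_p: float = np.nan
    residual_df: int = 0
    n_used: int = 0
    status: str = "ok"               # "ok" or "degenerate"

    def __post_init__(self) -> None:
        if self.beta3_levels is None:
            self.beta3_levels = {}


@dataclass(frozen=True)
class NormalityReport:
    probeset_id: str
    shapiro_p: float        # NaN when the test could not run (< 3 values)
    excluded: bool


def _design(x: np.ndarray, covars: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", "meth"] + list(covars.columns)
    X = np.column_stack([np.ones(len(x)), x, covars.to_numpy()]) \
        if covars.shape[1] else np.column_stack([np.ones(len(x)), x])
    return X, names


def fit_pair(
    y: pd.Series,
    x: pd.Series,
    pheno: PhenotypeTable,
    gene: str = "",
    probeset_id: str = "",
    probe_id: str = "",
    anova: str = "marginal",
) -> PairFit:
    """Fit one probeset-probe pair and test the methylation coefficient.

    ``y`` and ``x`` must be indexed by the same sample IDs as ``pheno``.
    Samples where either value is missing are dropped (pairwise deletion).
    Collinear or zero-variance designs, perfect fits, and insufficient
    sample counts produce ``status="degenerate"`` with ``beta1_p`` unset.
    """
    if set(y.index) != set(x.index) or not set(y.index) <= set(pheno.sample_ids):
        raise ValidationError("expression, methylation and phenotype sample IDs differ")
    fit = PairFit(gene=gene, probeset_id=probeset_id, probe_id=probe_id)
    aligned = pd.DataFrame({"y": y, "x": x.loc[y.index]}).dropna()
    fit.n_used = len(aligned)
    covars = pheno.design_columns(aligned.index)
    X, names = _design(aligned["x"].to_numpy(), covars)
    n, p = X.shape
    if n <= p:
        fit.status = "degenerate"
        logger.debug("pair (%s, %s): only %d samples for %d coefficients",
                     probeset_id, probe_id, n, p)
        return fit
    if np.linalg.matrix_rank(X) < p:
        fit.status = "degenerate"  # constant methylation or collinear covariates
        return fit

    yv = aligned["y"].to_numpy()
    res = sm.OLS(yv, X).fit()
    coef = dict(zip(names, res.params))
    fit.beta0 = coef["intercept"]
    fit.beta1 = coef["meth"]
    fit.beta2 = coef.get("ERpos", np.nan)
    fit.beta3_levels = {k: v for k, v in coef.items()
                        if k not in ("intercept", "meth", "ERpos")}
    fit.residual_df = int(res.df_resid)

    if res.ssr <= _SSR_REL_TOL * max(1.0, float(np.sum(yv ** 2))):
        fit.status = "degenerate"  # perfect fit: no residual variance to test against
        return fit

    if anova == "marginal":
        idx = names.index("meth")
        fit.beta1_se = float(res.bse[idx])
        fit.beta1_p = float(res.pvalues[idx])
    elif anova == "sequential":
        fit.beta1_se = float(res.bse[names.index("meth")])
        fit.beta1_p = _sequential_meth_p(yv, aligned["x"].to_numpy(), covars, res)
    else:
        raise ValidationError(f"unknown anova mode {anova!r}")
    return fit


def _sequential_meth_p(yv: np.ndarray, xv: np.ndarray,
                       covars: pd.DataFrame, full_res) -> float:
    """Type I (sequential) ANOVA p-value for methylation entered first.

    F = [SS(meth | intercept) / 1] / MSE(full model with ER and subtype).
    """
    n = len(yv)
    ssr_intercept_only = float(np.sum((yv - yv.mean()) ** 2))
    X1 = np.column_stack([np.ones(n), xv])
    res1 = sm.OLS(yv, X1).fit()
    ss_meth = ssr_intercept_only - float(res1.ssr)
    mse_full = full_res.ssr / full_res.df_resid
    f_stat = ss_meth / mse_full
    return float(scipy.stats.f.sf(f_stat, 1, full_res.df_resid))


def shapiro_filter(
    expr: OmicsMatrix,
    alpha_norm: float = 0.05,
    adjust: str = "raw",
) -> list[NormalityReport]:
    """Shapiro-Wilk normality screen on every expression probeset.

    A probeset is excluded when its (optionally Benjamini-Hochberg adjusted,
    ``adjust="bh"``) p-value falls below ``alpha_norm``.  Probesets with
    fewer than 3 non-missing values cannot be tested and are excluded with a
    logged reason.
    """
    if adjust not in ("raw", "bh"):
        raise ValidationError(f"unknown adjust mode {adjust!r}")
    ids, pvals, untestable = [], [], []
    for pid in expr.feature_ids:
        vals = expr.feature(pid).dropna().to_numpy()
        if len(vals) < 3:
            untestable.append(pid)
            logger.warning("probeset %s: %d values, cannot test normality; excluded",
                           pid, len(vals))
            continue
        if np.ptp(vals) == 0.0:
            # constant vector: Shapiro-Wilk is undefined; treat as non-normal
            ids.append(pid)
            pvals.append(0.0)
            continue
        ids.append(pid)
        pvals.append(float(scipy.stats.shapiro(vals).pvalue))
    pvals = np.asarray(pvals, dtype=float)
    use = pvals if adjust == "raw" else multipletests(pvals, method="fdr_bh")[1]
    reports = [NormalityReport(pid, float(p), bool(p < alpha_norm))
               for pid, p in zip(ids, use)]
    reports += [NormalityReport(pid, float("nan"), True) for pid in untestable]
    reports.sort(key=lambda r: r.probeset_id)
    return reports


def fit_all_pairs(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    pheno: PhenotypeTable,
    annotations: Sequence[GeneAnnotation],
    normality_reports: Iterable[NormalityReport] | None = None,
    anova: str = "marginal",
) -> list[PairFit]:
    """Fit the m' x n pair grid of every gene.

    ``m'`` counts the gene's probesets surviving the normality filter (all
    of them when ``normality_reports`` is None).  Output order is
    deterministic: lexicographic in (gene, probeset, probe).  Genes whose
    probesets are all excluded produce no pairs and are logged.
    """
    sample_set = set(pheno.sample_ids)
    if set(expr.sample_ids) != sample_set or set(meth.sample_ids) != sample_set:
        raise ValidationError("expression/methylation/phenotype sample sets differ")
    excluded = {r.probeset_id for r in normality_reports or [] if r.excluded}

    fits: list[PairFit] = []
    for ann in sorted(annotations, key=lambda a: a.gene):
        surviving = [ps for ps in sorted(ann.probesets) if ps not in excluded]
        if not surviving:
            logger.info("gene %s: all %d probesets excluded by normality filter",
                        ann.gene, ann.m)
            continue
        for ps in surviving:
            y = expr.feature(ps)
            for pr in sorted(ann.probes):
                fits.append(fit_pair(y, meth.feature(pr), pheno,
                                     gene=ann.gene, probeset_id=ps,
                                     probe_id=pr, anova=anova))
    return fits


def pair_fits_frame(fits: Iterable[PairFit]) -> pd.DataFrame:
    """Tabular view of pair fits, one row per pair."""
    rows = [
        {
            "gene": f.gene, "probeset_id": f.probeset_id, "probe_id": f.probe_id,
            "beta0": f.beta0, "beta1": f.beta1, "beta2": f.beta2,
            "beta1_se": f.beta1_se, "beta1_p": f.beta1_p,
            "residual_df": f.residual_df, "n_used": f.n_used, "status": f.status,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows, columns=["gene", "probeset_id", "probe_id", "beta0", "beta1",
                       "beta2", "beta1_se", "beta1_p", "residual_df",
                       "n_used", "status"],
    )


def pair_fits_from_frame(frame: pd.DataFrame) -> list[PairFit]:
    """Rebuild PairFit objects from a pair_fits table (inverse of
    :func:`pair_fits_frame`, minus the subtype coefficient details)."""
    return [
        PairFit(gene=r.gene, probeset_id=r.probeset_id, probe_id=r.probe_id,
                beta0=r.beta0, beta1=r.beta1, beta2=r.beta2,
                beta1_se=r.beta1_se, beta1_p=r.beta1_p,
                residual_df=int(r.residual_df), n_used=int(r.n_used),
                status=r.status)
        for r in frame.itertuples(index=False)
    ]
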