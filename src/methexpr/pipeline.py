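"""End-to-end orchestration: (simulate | load) -> normality filter -> pair
fits -> gene lists -> hubs -> methylation states, with a reproducibility
manifest.

A single :class:`RunConfig` carries every threshold of the analysis; the
defaults are the study's values (alpha 0.05, length cuts 2 probesets / 20
probes, significant-pair fractions 15% / 30%, coefficient cuts 0.5 and 1.0,
housekeeping level 8, eight hubs).  Runs are deterministic given the seed:
rerunning with the same config yields byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as mio
from .errors import ValidationError
from .methstate import (call_probe_states, flag_low_expression,
                        meth_summary_frame, probe_states_frame,
                        summarize_gene_meth)
from .model import fit_all_pairs, pair_fits_frame, shapiro_filter
from .network import build_subnetwork, degree_table, hub_profile, identify_hubs
from .simulate import (SyntheticConfig, generate_dataset, generate_edge_list,
                       truth_confusion)
from .summary import (build_lists, coeff_filter_table, gene_lists_frame,
                      gene_summary_frame, summarize_all_genes)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Exactly one of ``simulate`` (a :class:`SyntheticConfig` or its mapping)
    or the four data paths must be provided.
    """

    simulate: SyntheticConfig | None = None
    expr_path: str | None = None
    meth_path: str | None = None
    pheno_path: str | None = None
    annot_path: str | None = None
    edges_path: str | None = None

    alpha: float = 0.05
    alpha_norm: float = 0.05
    normality_adjust: str = "raw"          # "raw" | "bh"
    anova: str = "marginal"                # "marginal" | "sequential"
    probeset_cut: int = 2
    probe_cut: int = 20
    long_frac: float = 0.15
    short_frac: float = 0.30
    coeff_cuts: tuple[float, ...] = (0.5, 1.0)
    coeff_cut_final: float = 0.5
    housekeeping_threshold: float = 8.0
    hub_mode: str = "top_k"                # "top_k" | "degree_min"
    hub_k: int = 8
    hub_degree_min: int | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "alpha_norm"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("probeset_cut", "probe_cut", "hub_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("long_frac", "short_frac"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if any(c <= 0 for c in self.coeff_cuts) or self.coeff_cut_final <= 0:
            raise ValidationError("coefficient cutoffs must be positive")
        has_paths = all(p is not None for p in
                        (self.expr_path, self.meth_path, self.pheno_path,
                         self.annot_path))
        if (self.simulate is None) == (not has_paths):
            raise ValidationError(
                "provide either a simulate block or all four data paths"
            )
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "coeff_cuts" in raw:
            raw["coeff_cuts"] = tuple(float(c) for c in raw["coeff_cuts"])
        cfg = cls(**raw)
        if sim is not None:
            if isinstance(sim, SyntheticConfig):
                cfg.simulate = sim
            else:
                for key in ("m_range", "n_range", "beta0_range",
                            "meth_mu_range", "beta3_vec"):
                    if key in sim:
                        sim[key] = tuple(sim[key])
                cfg.simulate = SyntheticConfig(**sim)
        return cfg

    def to_mapping(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        out["coeff_cuts"] = list(self.coeff_cuts)
        return out


@dataclass
class PipelineResult:
    """In-memory bundle of one run; ``tables`` is what lands on disk."""

    tables: dict[str, pd.DataFrame]
    gene_lists: Any
    manifest: dict[str, Any]
    truth: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import scipy
    import statsmodels

    from . import __version__
    return {
        "methexpr": __version__, "numpy": numpy.__version__,
        "scipy": scipy.__version__, "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages in order and optionally write the result bundle.

    Any stage failure propagates with the stage name prepended.  The
    manifest records the config, seed, library versions, per-stage timings,
    and the filter-count audit table.
    """
    config.validate()
    manifest: dict[str, Any] = {"config": config.to_mapping(),
                                "seed": config.seed, "versions": _versions()}
    timings: dict[str, float] = {}
    truth = confusion = None

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    with stage("data"):
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            ds = generate_dataset(sim_cfg)
            expr, meth, pheno, annotations = (ds.expression, ds.methylation,
                                              ds.phenotypes, ds.annotations)
            truth = ds.truth
            manifest["n_expression_values_clipped"] = ds.n_clipped
        else:
            expr = mio.read_matrix(config.expr_path)
            meth = mio.read_matrix(config.meth_path)
            pheno = mio.read_phenotypes(config.pheno_path)
            annotations = mio.read_annotation(config.annot_path)

    with stage("normality_filter"):
        reports = shapiro_filter(expr, config.alpha_norm, config.normality_adjust)
        n_excluded = sum(r.excluded for r in reports)
        manifest["n_probesets_excluded_by_normality"] = n_excluded

    with stage("fit"):
        fits = fit_all_pairs(expr, meth, pheno, annotations, reports,
                             anova=config.anova)
        manifest["n_pairs_fit"] = len(fits)
        manifest["n_pairs_degenerate"] = sum(f.status != "ok" for f in fits)

    with stage("summarize"):
        summaries = summarize_all_genes(
            fits, annotations, config.alpha, config.long_frac,
            config.short_frac, config.probeset_cut, config.probe_cut)
        lists = build_lists(summaries, fits, config.alpha, config.coeff_cut_final)
        coeff_table = coeff_filter_table(fits, config.coeff_cuts, config.alpha)
        manifest["filter_counts"] = coeff_table.to_dict(orient="records")
        manifest["gene_list_sizes"] = {
            name: len(getattr(lists, name))
            for name in ("pos_long", "pos_short", "neg_long", "neg_short",
                         "pos_merged", "neg_merged", "pos_final", "neg_final",
                         "all_final")
        }
        if truth is not None:
            # genes whose every probeset failed the normality screen have no
            # summary; score recovery over the genes that were analyzable
            analyzable = truth[truth["gene"].isin({s.gene for s in summaries})]
            manifest["n_truth_genes_unanalyzable"] = len(truth) - len(analyzable)
            confusion = truth_confusion(summaries, analyzable)

    with stage("hubs"):
        annotated = {a.gene for a in annotations}
        input_genes = set(lists.all_final)
        if config.edges_path is not None:
            edges = mio.read_edge_list(config.edges_path)
        elif len(input_genes) >= max(config.hub_k, 5):
            edges = generate_edge_list(input_genes, seed=config.seed)
        else:
            logger.info("hub stage skipped: %d final genes and no edge list",
                        len(input_genes))
            edges = None
        if edges is not None:
            graph = build_subnetwork(edges, input_genes)
            hub_reports = identify_hubs(graph, config.hub_mode, config.hub_k,
                                        config.hub_degree_min)
        else:
            hub_reports = []
        hub_genes = {h.gene for h in hub_reports if h.is_hub}

    with stage("methstate"):
        meth_genes = sorted((input_genes | hub_genes) & annotated)
        states = call_probe_states(meth, annotations, meth_genes, config.alpha)
        by_gene: dict[str, list] = {}
        for s in states:
            by_gene.setdefault(s.gene, []).append(s)
        meth_summaries = {g: summarize_gene_meth(sts) for g, sts in by_gene.items()}
        expr_flags = flag_low_expression(expr, meth_genes, annotations,
                                         config.housekeeping_threshold)

    with stage("report"):
        profile = hub_profile([h for h in hub_reports if h.is_hub], lists,
                              meth_summaries, expr_flags)
        tables = {
            "pair_fits": pair_fits_frame(fits),
            "gene_summary": gene_summary_frame(summaries),
            "significant_genes": gene_lists_frame(lists),
            "coeff_filters": coeff_table,
            "probe_states": probe_states_frame(states),
            "gene_meth_summary": meth_summary_frame(meth_summaries.values()),
            "hub_degrees": degree_table(hub_reports),
            "hub_report": profile,
        }
        if truth is not None:
            tables["truth"] = truth
            tables["confusion"] = confusion.reset_index()

    manifest["stage_seconds"] = timings
    result = PipelineResult(tables=tables, gene_lists=lists, manifest=manifest,
                            truth=truth, confusion=confusion)
    if out_dir is not None:
        out_dir = Path(out_dir)
        mio.write_results(tables, out_dir)
        with open(out_dir / "run_manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return result
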