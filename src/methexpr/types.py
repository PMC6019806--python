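"""Core in-memory containers for the expression/methylation analysis.

The pipeline operates on four kinds of objects: feature-by-sample numeric
matrices (:class:`OmicsMatrix`), a sample phenotype table
(:class:`PhenotypeTable`), a gene-to-feature annotation
(:class:`GeneAnnotation`), and an undirected interaction edge list
(:class:`EdgeList`).  Matrices and phenotypes are thin, validated wrappers
around :class:`pandas.DataFrame`; annotations and edges are plain
dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ValidationError

ER_LEVELS = ("ERneg", "ERpos")
SUBTYPE_LEVELS = ("Luminal", "BasalA", "BasalB")

#: Synonyms accepted in phenotype files and normalized on read.
ER_SYNONYMS = {
    "ER+": "ERpos", "ERPOS": "ERpos", "ERpos": "ERpos", "POSITIVE": "ERpos",
    "ER-": "ERneg", "ER−": "ERneg", "ERNEG": "ERneg", "ERneg": "ERneg",
    "NEGATIVE": "ERneg",
}
SUBTYPE_SYNONYMS = {
    "LUMINAL": "Luminal", "Luminal": "Luminal",
    "BASALA": "BasalA", "BASAL A": "BasalA", "BasalA": "BasalA",
    "BASALB": "BasalB", "BASAL B": "BasalB", "BasalB": "BasalB",
}


@dataclass
class OmicsMatrix:
    """A feature x sample numeric matrix (expression probesets or methylation probes).

    ``data`` is indexed by feature ID with sample IDs as columns; missing
    values are NaN.  Both ID axes must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def feature(self, feature_id: str) -> pd.Series:
        """Return one feature's values across samples."""
        return self.data.loc[feature_id]


@dataclass
class PhenotypeTable:
    """Per-sample covariates: ER status and tumor subtype.

    ``data`` is indexed by sample ID with columns ``er_status`` (ERneg/ERpos)
    and ``subtype`` (Luminal/BasalA/BasalB).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"er_status", "subtype"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in phenotype table")
        bad_er = set(self.data["er_status"]) - set(ER_LEVELS)
        if bad_er:
            raise ValidationError(
                f"unknown ER status levels {sorted(bad_er)}; allowed: {list(ER_LEVELS)}"
            )
        bad_sub = set(self.data["subtype"]) - set(SUBTYPE_LEVELS)
        if bad_sub:
            raise ValidationError(
                f"unknown subtype levels {sorted(bad_sub)}; allowed: {list(SUBTYPE_LEVELS)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def design_columns(self, samples: Iterable[str]) -> pd.DataFrame:
        """Treatment-coded covariate columns for the given samples.

        ER reference level is ERneg; subtype reference is Luminal.  Indicator
        columns for levels absent from ``samples`` are dropped (reduced
        design), so the returned frame is always full rank in the covariates.
        """
        sub = self.data.loc[list(samples)]
        cols = {}
        if sub["er_status"].nunique() > 1:
            cols["ERpos"] = (sub["er_status"] == "ERpos").astype(float)
        present = [lv for lv in SUBTYPE_LEVELS if lv in set(sub["subtype"])]
        if len(present) > 1:
            # Luminal is the reference when present; otherwise the first
            # present level stands in so the design stays full rank.
            for level in present[1:]:
                cols[level] = (sub["subtype"] == level).astype(float)
        return pd.DataFrame(cols, index=sub.index)


@dataclass(frozen=True)
class GeneAnnotation:
    """Mapping of one gene to its expression probesets and methylation probes.

    ``m = len(probesets)`` and ``n = len(probes)`` define the gene's m x n
    pair grid and its long/short length class.
    """

    gene: str
    probesets: tuple[str, ...]
    probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("empty gene symbol")
        if len(set(self.probesets)) != len(self.probesets):
            raise ValidationError(f"duplicate probesets for gene {self.gene}")
        if len(set(self.probes)) != len(self.probes):
            raise ValidationError(f"duplicate probes for gene {self.gene}")
        if self.m < 1 or self.n < 1:
            raise ValidationError(
                f"gene {self.gene} needs >=1 probeset and >=1 probe (m={self.m}, n={self.n})"
            )

    @property
    def m(self) -> int:
        return len(self.probesets)

    @property
    def n(self) -> int:
        return len(self.probes)


INTERACTION_TYPES = ("binary_protein", "genetic", "regulatory", "other")


@dataclass(frozen=True)
class Edge:
    """One undirected interaction, stored with canonical node ordering."""

    node_a: str
    node_b: str
    interaction_type: str = "other"
    high_confidence: bool = True

    def __post_init__(self) -> None:
        if not self.node_a or not self.node_b:
            raise ValidationError("edge with empty node name")
        if self.node_a == self.node_b:
            raise ValidationError(f"self-loop on {self.node_a}")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValidationError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"allowed: {list(INTERACTION_TYPES)}"
            )
        if self.node_a > self.node_b:  # canonicalize undirected storage
            a, b = self.node_a, self.node_b
            object.__setattr__(self, "node_a", b)
            object.__setattr__(self, "node_b", a)

    @property
    def nodes(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


@dataclass
class EdgeList:
    """A set of undirected, canonicalized edges plus known intermediate nodes."""

    edges: set[Edge] = field(default_factory=set)
    intermediate_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.update(e.nodes)
        return out
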