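"""Reading and writing of all on-disk artifacts.

All files are delimited text: TSV by default, CSV when the extension is
``.csv``.  Matrices are features x samples with a header row of sample IDs
and the feature ID in the first column.  Missing values are the literal
``NA`` or an empty cell.  Output tables carry documented headers and are
written with a fixed float format so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError
from .types import (
    ER_SYNONYMS,
    INTERACTION_TYPES,
    SUBTYPE_SYNONYMS,
    Edge,
    EdgeList,
    GeneAnnotation,
    OmicsMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

#: Float format used for every numeric output column (determinism contract).
FLOAT_FORMAT = "%.10g"

_NA_VALUES = ["", "NA"]


def _sep(path: Path | str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path: str | Path, orientation: str = "features_as_rows") -> OmicsMatrix:
    """Read a feature x sample matrix from delimited text.

    Non-numeric cells become missing values; duplicate feature or sample IDs
    are rejected.  ``orientation`` only accepts ``"features_as_rows"``.
    """
    if orientation != "features_as_rows":
        raise ValidationError(f"unsupported orientation {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=_sep(path), index_col=0,
            na_values=_NA_VALUES, keep_default_na=False, dtype=str,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from None
    if df.columns.size == 0:
        raise ParseError(f"{path}: malformed header (no sample columns)")
    # Non-numeric cells -> NaN, per the missing-value convention.
    values = df.apply(pd.to_numeric, errors="coerce")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        return OmicsMatrix(values)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep=_sep(path), float_format=FLOAT_FORMAT, na_rep="NA")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the per-sample ER status / subtype table.

    Level synonyms from the common vocabulary ("ER+", "Basal B", ...) are
    normalized; unknown levels raise a validation error that lists the
    allowed values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, na_values=_NA_VALUES,
                     keep_default_na=False)
    required = ["sample_id", "er_status", "subtype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def norm_er(v: str) -> str:
        key = str(v).strip()
        if key in ER_SYNONYMS:
            return ER_SYNONYMS[key]
        if key.upper() in ER_SYNONYMS:
            return ER_SYNONYMS[key.upper()]
        raise ValidationError(
            f"{path}: unknown ER status {v!r}; allowed: ER+, ER-, ERpos, ERneg"
        )

    def norm_subtype(v: str) -> str:
        key = str(v).strip()
        if key in SUBTYPE_SYNONYMS:
            return SUBTYPE_SYNONYMS[key]
        if key.upper() in SUBTYPE_SYNONYMS:
            return SUBTYPE_SYNONYMS[key.upper()]
        raise ValidationError(
            f"{path}: unknown subtype {v!r}; allowed: Luminal, Basal A, Basal B"
        )

    out = pd.DataFrame(
        {
            "er_status": df["er_status"].map(norm_er).to_numpy(),
            "subtype": df["subtype"].map(norm_subtype).to_numpy(),
        },
        index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
    )
    return PhenotypeTable(out)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pheno.data.to_csv(path, sep=_sep(path))


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a long-format gene annotation: columns gene, feature_id, feature_kind.

    ``feature_kind`` is ``probeset`` or ``probe``.  A feature mapped to two
    genes is a validation error; genes lacking probesets or probes are
    dropped with a logged warning.  Returned list is sorted by gene symbol.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, na_values=_NA_VALUES,
                     keep_default_na=False)
    if df.empty and df.columns.size == 0:
        return []
    required = ["gene", "feature_id", "feature_kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad_kind = set(df["feature_kind"]) - {"probeset", "probe"}
    if bad_kind:
        raise ParseError(f"{path}: unknown feature_kind values {sorted(bad_kind)}")

    for kind in ("probeset", "probe"):
        sub = df[df["feature_kind"] == kind]
        owners = sub.groupby("feature_id")["gene"].nunique()
        multi = owners[owners > 1].index.tolist()
        if multi:
            raise ValidationError(
                f"{path}: {kind}s mapped to more than one gene: {multi[:5]}"
            )

    annotations: list[GeneAnnotation] = []
    for gene, grp in df.groupby("gene", sort=True):
        probesets = tuple(sorted(set(grp.loc[grp["feature_kind"] == "probeset", "feature_id"])))
        probes = tuple(sorted(set(grp.loc[grp["feature_kind"] == "probe", "feature_id"])))
        if not probesets or not probes:
            logger.warning(
                "gene %s dropped: %d probesets, %d probes (need >=1 of each)",
                gene, len(probesets), len(probes),
            )
            continue
        annotations.append(GeneAnnotation(str(gene), probesets, probes))
    return annotations


def write_annotation(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for ann in annotations:
        rows.extend((ann.gene, ps, "probeset") for ps in ann.probesets)
        rows.extend((ann.gene, pr, "probe") for pr in ann.probes)
    pd.DataFrame(rows, columns=["gene", "feature_id", "feature_kind"]).to_csv(
        path, sep=_sep(path), index=False
    )


_CONFIDENCE_TRUE = {"high", "true", "1", "yes"}
_CONFIDENCE_FALSE = {"low", "false", "0", "no"}


def read_edge_list(
    path: str | Path,
    allowed_types: set[str] | None = None,
    require_high_confidence: bool = False,
    intermediate_nodes: Iterable[str] = (),
) -> EdgeList:
    """Read an interaction edge list (columns node_a, node_b, interaction_type, confidence).

    Edges failing the type/confidence filter are excluded, duplicates are
    collapsed after canonical (undirected) ordering, and self-loops dropped.
    ``intermediate_nodes`` marks nodes added by the network source rather
    than present in the user's input gene list.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, na_values=_NA_VALUES,
                     keep_default_na=False)
    required = ["node_a", "node_b", "interaction_type", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if allowed_types is not None:
        bad = allowed_types - set(INTERACTION_TYPES)
        if bad:
            raise ValidationError(f"unknown interaction types in filter: {sorted(bad)}")

    edges: set[Edge] = set()
    n_self = n_filtered = 0
    for row in df.itertuples(index=False):
        conf = str(row.confidence).strip().lower()
        if conf in _CONFIDENCE_TRUE:
            high = True
        elif conf in _CONFIDENCE_FALSE:
            high = False
        else:
            raise ParseError(f"{path}: unrecognized confidence value {row.confidence!r}")
        itype = str(row.interaction_type).strip()
        if itype not in INTERACTION_TYPES:
            raise ParseError(f"{path}: unknown interaction_type {itype!r}")
        if str(row.node_a) == str(row.node_b):
            n_self += 1
            continue
        if allowed_types is not None and itype not in allowed_types:
            n_filtered += 1
            continue
        if require_high_confidence and not high:
            n_filtered += 1
            continue
        edges.add(Edge(str(row.node_a), str(row.node_b), itype, high))
    if n_self or n_filtered:
        logger.info("edge list %s: dropped %d self-loops, filtered %d edges",
                    path, n_self, n_filtered)
    return EdgeList(edges=edges, intermediate_nodes=set(intermediate_nodes))


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(
        (e.node_a, e.node_b, e.interaction_type, "high" if e.high_confidence else "low")
        for e in edge_list.edges
    )
    pd.DataFrame(rows, columns=["node_a", "node_b", "interaction_type", "confidence"]).to_csv(
        path, sep=_sep(path), index=False
    )


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write the pipeline's result tables as TSVs under ``out_dir``.

    ``tables`` maps a base name (e.g. ``pair_fits``) to its DataFrame.  The
    directory is created if absent; numeric content is formatted with a fixed
    float format so identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        dest = out_dir / f"{name}.tsv"
        tables[name].to_csv(dest, sep="\t", index=False,
                            float_format=FLOAT_FORMAT, na_rep="NA")
        written.append(dest)
    return written
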