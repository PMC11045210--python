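"""Data containers and text-format readers/writers.

The pipeline consumes three kinds of input:

* a normalized gene-expression matrix (genes x samples, TSV or CSV) with a
  binary tumor/normal sample annotation, either embedded as a ``class`` row
  or supplied as a separate two-column file;
* a disease->gene annotation map in GMT format, optionally backed by a
  minimal OBO ontology providing ``is_a`` edges;
* a survival table (sample, time, event).

Values are either linear-scale normalized expression (FPKM/RPKM-like,
non-negative) or already log2-transformed; the scale is always declared by
the caller, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"
_CLASSES = frozenset({TUMOR, NORMAL})
#: row/column ids recognised as an embedded label line in a matrix file
_LABEL_IDS = frozenset({"class", "label", "labels", "group"})

LINEAR = "linear"
LOG2 = "log2"
_SCALES = frozenset({LINEAR, LOG2})


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _normalize_label(raw: object, sample: str) -> str:
    lab = str(raw).strip().lower()
    if lab in ("tumour", "t", "case"):
        lab = TUMOR
    elif lab in ("n", "control", "healthy"):
        lab = NORMAL
    if lab not in _CLASSES:
        raise ValueError(
            f"sample {sample!r}: class label {raw!r} is not tumor/normal"
        )
    return lab


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with binary class labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``labels`` maps every sample id to ``"tumor"`` or ``"normal"``;
    ``scale`` declares whether values are linear or log2.
    """

    values: pd.DataFrame
    labels: pd.Series
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {sorted(_SCALES)}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == LINEAR and (arr < 0).any():
            raise ValueError("negative values under linear scale")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without class labels: {missing[:5]}")
        self.labels = self.labels.reindex(self.values.columns)
        bad = set(self.labels.unique()) - _CLASSES
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == TUMOR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == NORMAL])

    def gene_values(self, gene_id: str, group: str | None = None) -> np.ndarray:
        """Expression vector of one gene, optionally restricted to a class."""
        row = self.values.loc[gene_id]
        if group is None:
            return row.to_numpy(dtype=float)
        return row[self.labels == group].to_numpy(dtype=float)

    def log2_matrix(self, epsilon: float = 0.25) -> pd.DataFrame:
        """Matrix on log2 scale (pseudo-count ``epsilon`` applied when linear)."""
        if self.scale == LOG2:
            return self.values.copy()
        return np.log2(self.values + epsilon)

    def subset(self, genes=None, samples=None) -> "ExpressionDataset":
        vals = self.values
        if genes is not None:
            vals = vals.loc[list(genes)]
        if samples is not None:
            vals = vals[list(samples)]
        return ExpressionDataset(vals.copy(), self.labels.loc[vals.columns].copy(), self.scale)

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and self.labels.equals(other.labels)
        )


@dataclass
class AnnotationMap:
    """Disease term -> gene-set map with an optional ``is_a`` DAG."""

    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    dag_edges: frozenset[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for term, genes in self.term_to_genes.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"term {term!r} has no annotated genes")
            clean[term] = genes
        self.term_to_genes = clean
        if self.dag_edges is not None:
            self.dag_edges = frozenset(tuple(e) for e in self.dag_edges)
            _check_acyclic(self.dag_edges)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, term)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1 event, 0 censored)."""

    data: pd.DataFrame  # index: sample_id; columns: time, event

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        if (df["time"] <= 0).any():
            bad = df.index[df["time"] <= 0][0]
            raise ValueError(f"non-positive survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise ValueError(f"event for sample {bad!r} is not 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def times_events(self, samples) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data.loc[list(samples)]
        return sub["time"].to_numpy(float), sub["event"].to_numpy(int)


def _check_acyclic(edges) -> None:
    g = nx.DiGraph(list(edges))
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
    raise ValueError(f"is_a relation contains a cycle: {path}")


# ---------------------------------------------------------------------------
# expression matrices


def read_labels(path) -> pd.Series:
    """Two-column sample->class file; classes normalized to tumor/normal."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (sample, class)")
    first = str(df.iloc[0, 1]).strip().lower()
    if first in _LABEL_IDS or first in ("class", "status"):
        df = df.iloc[1:]
    samples = df.iloc[:, 0].astype(str).str.strip()
    labels = [
        _normalize_label(raw, s) for s, raw in zip(samples, df.iloc[:, 1])
    ]
    return pd.Series(labels, index=list(samples), name="class")


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    scale: str = LINEAR,
    labels_path=None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Parse a delimited expression matrix into an :class:`ExpressionDataset`.

    Labels come from ``labels_path`` when given, otherwise from an embedded
    row (or column, under ``samples_in_rows``) whose id is one of
    ``class/label/labels/group``. Duplicate gene rows collapse to the row
    with the highest mean (logged).
    """
    path = Path(path)
    if sep is None:
        sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "samples_in_rows":
        raw = raw.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    labels: pd.Series | None = None
    embedded = [i for i in raw.index if str(i).strip().lower() in _LABEL_IDS]
    if embedded:
        row = raw.loc[embedded[0]]
        labels = pd.Series(
            [_normalize_label(v, s) for s, v in row.items()],
            index=list(row.index),
        )
        raw = raw.drop(index=embedded)
    if labels_path is not None:
        labels = read_labels(labels_path)
    if labels is None:
        raise ValueError(
            f"{path}: no sample labels (provide labels_path or an embedded class row)"
        )

    probe = raw.apply(pd.to_numeric, errors="coerce")
    if probe.isna().any().any():
        mask = probe.isna()
        gene = mask.index[mask.any(axis=1)][0]
        sample = mask.columns[mask.loc[gene]][0]
        raise ValueError(
            f"{path}: non-numeric value {raw.loc[gene, sample]!r} at gene {gene!r}, sample {sample!r}"
        )
    # astype(float) is correctly rounded (pd.to_numeric's parser is not)
    values = raw.astype(float)

    if values.index.has_duplicates:
        n_before = len(values)
        means = values.mean(axis=1)
        order = np.argsort(-means.to_numpy())  # best rows first
        values = values.iloc[order]
        values = values[~values.index.duplicated(keep="first")]
        # restore first-appearance order of the surviving gene ids
        values = values.loc[[g for g in dict.fromkeys(raw.index) ]]
        logger.info("collapsed %d duplicate gene rows (kept max-mean row)", n_before - len(values))

    return ExpressionDataset(values, labels, scale)


def write_expression(ds: ExpressionDataset, path, labels_path=None) -> None:
    path = Path(path)
    # %.17g round-trips every IEEE double exactly
    ds.values.to_csv(path, sep=_sep_for(path), index_label="gene_id", float_format="%.17g")
    if labels_path is not None:
        ds.labels.rename("class").to_csv(labels_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# GMT annotation maps


def read_gmt(path) -> AnnotationMap:
    """Broad-dialect GMT: ``term<TAB>description<TAB>gene...`` per line."""
    term_to_genes: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            term, name, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} lists no genes")
            term_to_genes[term] = frozenset(genes)
            term_names[term] = name
    return AnnotationMap(term_to_genes, term_names)


def write_gmt(amap: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for term in amap.term_to_genes:
            genes = sorted(amap.term_to_genes[term])
            fh.write("\t".join([term, amap.name_of(term), *genes]) + "\n")


# ---------------------------------------------------------------------------
# OBO ontologies


def read_obo_isa(path) -> frozenset[tuple[str, str]]:
    """Extract (child, parent) ``is_a`` edges from an OBO flat file.

    Only id/name/is_a/is_obsolete are consumed; obsolete terms are skipped.
    A cycle in the ``is_a`` closure is a hard error naming one cycle.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    edges = frozenset(
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    )
    _check_acyclic(edges)
    return edges


# ---------------------------------------------------------------------------
# survival tables


def read_survival(path) -> SurvivalTable:
    """TSV/CSV with columns sample, time, event; incomplete rows are dropped."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)), dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: survival table needs sample, time, event columns")
    df = df.iloc[:, :3]
    df.columns = ["sample_id", "time", "event"]
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    incomplete = time.isna() | event.isna() | df["time"].isna() | df["event"].isna()
    n_drop = int(incomplete.sum())
    if n_drop:
        logger.info("dropped %d survival rows with missing time/event", n_drop)
    keep = ~incomplete
    out = pd.DataFrame(
        {
            # astype(float) parses correctly rounded; to_numeric does not
            "time": df["time"][keep].astype(float).to_numpy(),
            "event": event[keep].to_numpy(float),
        },
        index=pd.Index(df["sample_id"][keep].to_numpy(), name="sample_id"),
    )
    if not out["event"].isin([0.0, 1.0]).all():
        bad = out.index[~out["event"].isin([0.0, 1.0])][0]
        raise ValueError(f"{path}: event for sample {bad!r} is not 0/1")
    out["event"] = out["event"].astype(int)
    return SurvivalTable(out)


def write_survival(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")
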