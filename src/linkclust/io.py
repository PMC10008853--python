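"""Readers, writers and core containers for expression, ontology and constraint data.

External formats handled here:

* expression matrices: delimited text, first column gene id, remaining
  columns numeric features;
* ontologies: OBO 1.2 stanzas, ``is_a`` relations only (parsed with
  :mod:`obonet` into a child->parent :class:`networkx.DiGraph`);
* gene annotations: two-column delimited text (gene id, term id);
* pairwise constraints: four-column TSV (gene_a, gene_b, kind, source).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "OntologyGraph",
    "AnnotationMap",
    "ConstraintRecord",
    "ConstraintSet",
    "load_expression",
    "normalize_minmax",
    "load_ontology",
    "load_annotations",
    "compute_term_frequencies",
    "read_constraints",
    "write_constraints",
    "write_expression",
    "write_obo",
    "write_annotations",
    "write_labels",
    "read_labels",
]

KINDS = ("ML", "CL")
SOURCES = ("expression", "ontology")


class ParseError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """n genes x d features with stable gene identifiers.

    ``values`` holds expression levels in arbitrary units before
    normalization and in [0, 1] per feature afterwards.
    """

    gene_ids: list[str]
    values: np.ndarray  # (n, d) float64
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ParseError(f"duplicate gene ids: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            raise ParseError("expression matrix contains missing/non-finite values")
        if self.normalized and self.values.size:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("normalized matrix has values outside [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id}") from None


@dataclass
class OntologyGraph:
    """An ontology as a DAG of terms with child->parent ``is_a`` edges.

    ``term_frequency`` maps a term to its annotation frequency p(t) in
    (0, 1], propagated up the DAG (true-path rule), and is populated by
    :func:`load_annotations` or by the synthetic generator.
    """

    graph: nx.DiGraph  # edges child -> parent
    term_frequency: dict[str, float] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms on paths from ``term`` to the root(s), including ``term``."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term}")
        # child->parent edges: reachable-from == ontology ancestors
        return nx.descendants(self.graph, term) | {term}

    def subterms(self, term: str) -> set[str]:
        """All more-specific terms below ``term``, including ``term``."""
        if term not in self.graph:
            raise KeyError(f"unknown term: {term}")
        return nx.ancestors(self.graph, term) | {term}

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}


AnnotationMap = dict  # gene_id -> set of term ids


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True, order=True)
class ConstraintRecord:
    """A must-link or cannot-link pair, stored order-independently."""

    gene_a: str
    gene_b: str
    kind: str  # "ML" | "CL"
    source: str  # "expression" | "ontology"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair constraint: {self.gene_a}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown constraint kind: {self.kind!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown constraint source: {self.source!r}")
        a, b = _canonical_pair(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


class ConstraintSet:
    """A deduplicated collection of :class:`ConstraintRecord`.

    Iteration order is deterministic (sorted), so downstream sampling with a
    seeded RNG is reproducible.
    """

    def __init__(self, records: Iterable[ConstraintRecord] = ()) -> None:
        self._records: set[ConstraintRecord] = set(records)

    def add(self, record: ConstraintRecord) -> None:
        self._records.add(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ConstraintRecord]:
        return iter(sorted(self._records))

    def __contains__(self, record: ConstraintRecord) -> bool:
        return record in self._records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConstraintSet):
            return NotImplemented
        return self._records == other._records

    def pairs(self, kind: str | None = None, source: str | None = None) -> set[tuple[str, str]]:
        return {
            r.pair
            for r in self._records
            if (kind is None or r.kind == kind) and (source is None or r.source == source)
        }

    def filter(self, kind: str | None = None, source: str | None = None) -> "ConstraintSet":
        return ConstraintSet(
            r
            for r in self._records
            if (kind is None or r.kind == kind) and (source is None or r.source == source)
        )

    def discard_pair(self, pair: tuple[str, str]) -> None:
        pair = _canonical_pair(*pair)
        self._records = {r for r in self._records if r.pair != pair}

    def __repr__(self) -> str:  # pragma: no cover
        n_ml = len(self.pairs(kind="ML"))
        n_cl = len(self.pairs(kind="CL"))
        return f"ConstraintSet(ML={n_ml}, CL={n_cl})"


# ---------------------------------------------------------------------------
# expression matrices


def load_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a genes x features table; first column is the gene id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty expression file") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed table ({exc})") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: expression table has no data rows/columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from None
    if np.isnan(values).any():
        rows = sorted(df.index[np.isnan(values).any(axis=1)][:5])
        raise ParseError(f"{path}: missing values in rows {rows}")
    return ExpressionMatrix(gene_ids=[str(g) for g in df.index], values=values)


def normalize_minmax(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each feature to [0, 1]; constant features map to all-zeros."""
    if m.n < 2:
        raise ValueError("min-max normalization needs at least 2 genes")
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    values = (m.values - lo) / safe
    values[:, span == 0] = 0.0
    return replace(m, values=values, normalized=True)


def write_expression(m: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids)
    df.columns = [f"f{i}" for i in range(m.d)]
    df.index.name = "gene"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


# ---------------------------------------------------------------------------
# ontology + annotations


def load_ontology(path: str | Path, namespace: str | None = None) -> OntologyGraph:
    """Parse OBO stanzas into a child->parent DAG, keeping is_a edges only.

    Obsolete terms are skipped; a cycle aborts the load with one offending
    term named. ``namespace`` optionally restricts the graph to terms of
    one OBO namespace (e.g. "biological_process"); edges into dropped
    terms are dropped with them.
    """
    multigraph = obonet.read_obo(str(path), ignore_obsolete=True)
    keep = set(multigraph.nodes)
    if namespace is not None:
        keep = {
            t
            for t, attrs in multigraph.nodes(data=True)
            if attrs.get("namespace") == namespace
        }
        if not keep:
            raise ParseError(f"no terms in namespace {namespace!r}")
    graph = nx.DiGraph()
    graph.add_nodes_from(keep)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a" and child in keep and parent in keep:
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ParseError(f"ontology contains a cycle through term {cycle[0][0]!r}")
    return OntologyGraph(graph=graph)


def load_annotations(path: str | Path, ontology: OntologyGraph, delimiter: str = "\t") -> AnnotationMap:
    """Load gene->term annotations and populate the ontology's term frequencies.

    The frequency p(t) follows the true-path rule: a gene annotated to t
    counts toward t and every ancestor of t; the denominator is the number
    of genes carrying at least one annotation in this map.
    """
    df = pd.read_csv(
        path, sep=delimiter, header=None, names=["gene", "term"], dtype=str, comment="!"
    )
    unknown = df.loc[~df["term"].isin(ontology.terms)]
    if len(unknown):
        rows = unknown.head(5).to_dict("records")
        raise ParseError(f"annotation terms not in ontology: {rows}")
    mapping: AnnotationMap = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    compute_term_frequencies(mapping, ontology)
    return mapping


def compute_term_frequencies(mapping: AnnotationMap, ontology: OntologyGraph) -> None:
    """(Re)compute p(t) for every ontology term from an annotation map."""
    n_annotated = len(mapping)
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for terms in mapping.values():
        closed: set[str] = set()
        for t in terms:
            closed |= ontology.ancestors(t)
        for t in closed:
            counts[t] += 1
    ontology.term_frequency = {
        t: counts[t] / n_annotated for t in ontology.terms if counts[t] > 0
    }


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Serialize the DAG as minimal OBO 1.2 stanzas (id / is_a only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(ontology.graph.nodes):
            fh.write(f"\n[Term]\nid: {term}\n")
            for parent in sorted(ontology.graph.successors(term)):
                fh.write(f"is_a: {parent}\n")


def write_annotations(mapping: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_labels(gene_ids: list[str], labels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\n")
        for g, lab in zip(gene_ids, labels):
            fh.write(f"{g}\t{int(lab)}\n")


def read_labels(path: str | Path, gene_ids: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"gene": str, "label": int})
    label_of = dict(zip(df["gene"], df["label"]))
    missing = [g for g in gene_ids if g not in label_of]
    if missing:
        raise ParseError(f"labels missing for genes: {missing[:5]}")
    return np.array([label_of[g] for g in gene_ids], dtype=int)


# ---------------------------------------------------------------------------
# constraints


def write_constraints(path: str | Path, constraints: ConstraintSet) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tkind\tsource\n")
        for rec in constraints:
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.kind}\t{rec.source}\n")


def read_constraints(path: str | Path) -> ConstraintSet:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    expected = ["gene_a", "gene_b", "kind", "source"]
    if list(df.columns) != expected:
        raise ParseError(f"constraint file columns {list(df.columns)} != {expected}")
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(ConstraintRecord(row.gene_a, row.gene_b, row.kind, row.source))
        except ValueError as exc:
            raise ParseError(f"bad constraint row {tuple(row)}: {exc}") from None
    return ConstraintSet(records)
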