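"""Protein→term annotation tables, True-Path-Rule propagation, term
selection and the binary label matrix.

Under the True Path Rule a protein annotated with a term is implicitly
annotated with every ancestor of that term, so annotation sets are closed
upward before counting term frequencies or building labels. Term selection
keeps, per sub-ontology, the terms annotated to at least ``min_count``
proteins (the defaults follow the study design: 25 for CC, 150 for BP,
25 for MF), ordered most-frequent-first with lexicographic tie-breaks so a
run is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import EmptyIndexError, ParseError
from .ontology import OntologyGraph, TermIndex

logger = logging.getLogger(__name__)

MIN_COUNT_DEFAULTS = {"CC": 25, "BP": 150, "MF": 25}

#: GAF qualifier values that negate an annotation; such rows are dropped.
_NEGATIVE_QUALIFIERS = ("NOT",)


@dataclass
class AnnotationTable:
    """Map protein id → set of term ids, optionally TPR-propagated."""

    proteins: dict = field(default_factory=dict)
    propagated: bool = False

    def __len__(self):
        return len(self.proteins)

    def __getitem__(self, protein):
        return self.proteins[protein]

    def __contains__(self, protein):
        return protein in self.proteins

    def items(self):
        return self.proteins.items()

    def term_counts(self) -> dict:
        """Number of proteins annotated with each term."""
        counts: dict = {}
        for terms in self.proteins.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts


def read_annotations(
    path,
    graph: OntologyGraph,
    fmt: str = "tsv",
    evidence_codes: set | None = None,
) -> AnnotationTable:
    """Read protein→term annotations from a two-column TSV or a GAF 2.x file.

    Alternate term ids are resolved to primary ids; annotations to terms
    absent from ``graph`` are dropped with a warning (real association files
    contain stale identifiers). GAF rows with a NOT qualifier are dropped.
    ``evidence_codes``, when given, restricts GAF rows to those codes; by
    default all are accepted.
    """
    if fmt not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    table: dict = {}
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            if fmt == "tsv":
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ParseError(
                        f"expected two tab-separated columns, got {line!r}",
                        line=lineno,
                    )
                protein, term = parts
            else:
                parts = line.split("\t")
                if len(parts) < 15:
                    raise ParseError(
                        f"GAF row has {len(parts)} columns, expected >= 15",
                        line=lineno,
                    )
                qualifier = parts[3]
                if any(q in qualifier.split("|") for q in _NEGATIVE_QUALIFIERS):
                    continue
                if evidence_codes is not None and parts[6] not in evidence_codes:
                    continue
                protein, term = parts[1], parts[4]
            if term not in graph:
                dropped += 1
                logger.warning(
                    "dropping annotation %s -> %s: term not in ontology",
                    protein,
                    term,
                )
                continue
            table.setdefault(protein, set()).add(graph.resolve(term))
    if dropped:
        logger.warning("dropped %d annotations to unknown terms", dropped)
    return AnnotationTable(proteins=table, propagated=False)


def propagate_true_path(graph: OntologyGraph, table: AnnotationTable) -> AnnotationTable:
    """Close every protein's term set under ancestors (idempotent)."""
    out: dict = {}
    for protein, terms in table.items():
        closed = set(terms)
        for t in terms:
            closed.update(graph.ancestors(t))
        out[protein] = closed
    return AnnotationTable(proteins=out, propagated=True)


def select_terms(
    table: AnnotationTable,
    graph: OntologyGraph,
    namespace: str,
    min_count: int | None = None,
) -> TermIndex:
    """Select the frequent terms of one sub-ontology.

    Terms of ``namespace`` annotated (after propagation) to at least
    ``min_count`` proteins, sorted by descending count then term id. The
    boundary is inclusive.
    """
    if not table.propagated:
        raise ValueError("term selection requires a TPR-propagated table")
    if min_count is None:
        min_count = MIN_COUNT_DEFAULTS[namespace]
    counts = table.term_counts()
    eligible = [
        (t, c)
        for t, c in counts.items()
        if c >= min_count and graph.namespace.get(t) == namespace
    ]
    if not eligible:
        raise EmptyIndexError(
            f"no {namespace} term reaches min_count={min_count}; lower the threshold"
        )
    eligible.sort(key=lambda tc: (-tc[1], tc[0]))
    index = TermIndex([t for t, _ in eligible], namespace=namespace)
    logger.info(
        "selected %d %s terms at min_count=%d", len(index), namespace, min_count
    )
    return index


@dataclass
class LabelMatrix:
    """Binary proteins × selected-terms annotation matrix, TPR-closed."""

    proteins: list
    index: TermIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.proteins), len(self.index)):
            raise ValueError(
                f"label matrix shape {self.values.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.index)} terms"
            )

    @property
    def shape(self):
        return self.values.shape

    def row(self, protein) -> np.ndarray:
        return self.values[self.proteins.index(protein)]

    def term_counts(self) -> Mapping[str, int]:
        """Annotated-protein count per selected term, from the matrix itself."""
        sums = self.values.sum(axis=0)
        return {t: int(sums[i]) for i, t in enumerate(self.index)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.proteins, columns=self.index.terms)


def build_label_matrix(table: AnnotationTable, index: TermIndex) -> LabelMatrix:
    """Binary label vectors over the selected terms.

    One row per protein annotated with at least one selected term; proteins
    whose propagated set misses the selected terms entirely are excluded.
    """
    if not table.propagated:
        raise ValueError("label matrix requires a TPR-propagated table")
    proteins = []
    rows = []
    for protein in sorted(table.proteins):
        terms = table[protein]
        row = np.fromiter(
            (1 if t in terms else 0 for t in index), dtype=np.int8, count=len(index)
        )
        if row.any():
            proteins.append(protein)
            rows.append(row)
    if not proteins:
        raise EmptyIndexError(
            "every protein lost all annotations under the selected terms; "
            "lower min_count"
        )
    logger.info("label matrix: %d proteins x %d terms", len(proteins), len(index))
    return LabelMatrix(proteins=proteins, index=index, values=np.vstack(rows))
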