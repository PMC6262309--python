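"""Gene-function annotations and the weighted-shared-functions (WSF) score.

Genes are associated with functional categories (typically Gene Ontology
terms).  A function shared by few genes is more informative than one shared
by many, so each function carries a significance equal to the inverse of the
number of genes annotated to it:

    sig(f) = 1 / |Gene(f)|

and the functional similarity between two genes i and j is the total
significance of the functions they share:

    F(i, j) = sum over f in terms(i) ∩ terms(j) of sig(f)

This score is used to weight the edges of a protein-interaction network
(see :mod:`ricewalk.netbuild`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError

__all__ = [
    "AnnotationIndex",
    "load_annotations",
    "term_significance",
    "shared_function_score",
    "propagate_to_ancestors",
]

#: GO accession style token; used for header auto-detection in two-column
#: files, not to restrict the accepted term vocabulary.
_TERM_TOKEN = re.compile(r"^\S+$")
_GO_STYLE = re.compile(r"^GO:\d+$")


@dataclass(frozen=True)
class AnnotationIndex:
    """Bidirectional gene ↔ function-term mapping.

    Invariants: ``g in term_to_genes[t]`` iff ``t in gene_to_terms[g]``;
    every term maps to at least one gene; genes with no annotations are
    absent from ``gene_to_terms``.
    """

    gene_to_terms: Mapping[str, frozenset[str]]
    term_to_genes: Mapping[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationIndex":
        """Build an index from (gene, term) pairs, deduplicating."""
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            if not gene or not term or any(c.isspace() for c in gene + term):
                raise DataError(f"invalid (gene, term) pair: ({gene!r}, {term!r})")
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        return cls(
            gene_to_terms={g: frozenset(ts) for g, ts in g2t.items()},
            term_to_genes={t: frozenset(gs) for t, gs in t2g.items()},
        )

    def terms_of(self, gene: str) -> frozenset[str]:
        """Terms annotated to ``gene``; empty set for unannotated genes."""
        return self.gene_to_terms.get(gene, frozenset())

    def genes_of(self, term: str) -> frozenset[str]:
        if term not in self.term_to_genes:
            raise DataError(f"unknown function term: {term!r}")
        return self.term_to_genes[term]

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_terms)

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    def pairs(self) -> Iterable[tuple[str, str]]:
        for gene in sorted(self.gene_to_terms):
            for term in sorted(self.gene_to_terms[gene]):
                yield gene, term


def _parse_two_column(lines: Iterable[str]) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise DataError(
                f"line {lineno}: expected two columns (gene<TAB>term), got {line!r}"
            )
        gene, term = fields[0].strip(), fields[1].strip()
        # Header auto-detection: a first data row whose second field is not a
        # plain token (or is a literal column name) is treated as a header.
        if lineno == 1 and not pairs:
            if not _TERM_TOKEN.match(term) or term.lower() in {"term", "go_id", "go"}:
                continue
        if not gene or not term:
            raise DataError(f"line {lineno}: empty gene or term field")
        pairs.append((gene, term))
    return pairs


def _parse_gaf(
    lines: Iterable[str],
    exclude_not: bool = True,
    aspects: set[str] | None = None,
    evidence_codes: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Extract (DB Object ID, GO ID) pairs from GAF 2.x lines.

    GAF columns (1-based): 2 = DB Object ID, 4 = Qualifier, 5 = GO ID,
    7 = Evidence Code, 9 = Aspect.  All aspects and evidence codes are kept
    unless filters are given.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise DataError(
                f"line {lineno}: GAF record has {len(fields)} columns, expected >= 5"
            )
        gene, qualifier, term = fields[1].strip(), fields[3].strip(), fields[4].strip()
        if not gene or not term:
            raise DataError(f"line {lineno}: empty DB Object ID or GO ID")
        if exclude_not and "NOT" in qualifier.split("|"):
            continue
        if evidence_codes is not None:
            code = fields[6].strip() if len(fields) > 6 else ""
            if code not in evidence_codes:
                continue
        if aspects is not None:
            aspect = fields[8].strip() if len(fields) > 8 else ""
            if aspect not in aspects:
                continue
        pairs.append((gene, term))
    return pairs


def load_annotations(
    path: str | Path,
    format: str = "two_column",
    *,
    exclude_not: bool = True,
    aspects: set[str] | None = None,
    evidence_codes: set[str] | None = None,
) -> AnnotationIndex:
    """Read gene-function annotations into an :class:`AnnotationIndex`.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"gaf"`` for GAF 2.x, ``"two_column"`` for ``gene<TAB>term`` rows.
    exclude_not
        Drop GAF records whose qualifier contains ``NOT`` (default True).
    aspects, evidence_codes
        Optional GAF include-filters (e.g. ``{"P"}``, ``{"EXP", "IDA"}``).
        ``None`` keeps everything.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read annotation file {path}: {exc}") from exc
    lines = text.splitlines()
    if format == "two_column":
        pairs = _parse_two_column(lines)
    elif format == "gaf":
        pairs = _parse_gaf(
            lines,
            exclude_not=exclude_not,
            aspects=aspects,
            evidence_codes=evidence_codes,
        )
    else:
        raise DataError(f"unknown annotation format: {format!r}")
    if not pairs:
        raise DataError(f"zero usable records in annotation file {path}")
    return AnnotationIndex.from_pairs(pairs)


def term_significance(index: AnnotationIndex, term: str) -> float:
    """Significance of one function: ``1 / |Gene(term)|``, in (0, 1]."""
    return 1.0 / len(index.genes_of(term))


def shared_function_score(index: AnnotationIndex, i: str, j: str) -> float:
    """WSF functional similarity ``F(i, j)``.

    Sum of :func:`term_significance` over the function terms shared by the
    two genes.  Genes absent from the index have no functions, so any pair
    involving one scores 0.
    """
    shared = index.terms_of(i) & index.terms_of(j)
    # sorted order makes the float summation order (hence the result)
    # reproducible and symmetric in i, j
    return sum(1.0 / len(index.term_to_genes[t]) for t in sorted(shared))


def propagate_to_ancestors(index: AnnotationIndex, obo_path: str | Path) -> AnnotationIndex:
    """Optional true-path propagation: annotate each gene to all ancestors
    of its direct terms.

    Requires an OBO ontology file; terms missing from the ontology keep only
    their direct annotation.  Uses ``is_a``/``part_of`` edges as read by
    ``obonet``.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(str(obo_path))
    pairs: list[tuple[str, str]] = []
    for gene, terms in index.gene_to_terms.items():
        expanded = set(terms)
        for t in terms:
            if t in graph:
                # obonet edges point child -> parent, so graph-descendants
                # of a term are its ontology ancestors
                expanded |= nx.descendants(graph, t)
        pairs.extend((gene, t) for t in expanded)
    return AnnotationIndex.from_pairs(pairs)
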