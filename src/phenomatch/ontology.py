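"""Merged cross-species phenotype ontology.

The scoring pipeline works on a single rooted DAG that contains both
human-phenotype (HP) and mammalian-phenotype (MP) branches connected through
shared ancestor terms, so that an HP term and an MP term can have an
informative common subsumer.  This module parses such a graph from an OBO
flat file, exposes the (reflexive) ancestor closure, computes annotation-based
information content (IC) over a corpus of annotated entities, and finds the
most-informative common ancestor (MICA) of a term pair.

Conventions
-----------
* Only ``is_a`` edges are honoured; other relationship types are ignored.
* Ancestor sets are *reflexive*: a term is an ancestor of itself.  This makes
  the Jaccard similarity of a term with itself equal to 1.
* IC uses natural logarithms.  A term annotated (directly or via descendants)
  by ``c`` of ``N`` corpus entities has ``IC = -ln(c / N)``; a never-annotated
  term gets the maximum ``ln(N)`` (frequency treated as 1) so IC stays finite.
  Roots are fixed at IC 0.
"""

from __future__ import annotations

import io
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "Term",
    "Ontology",
    "ICTable",
    "OntologyStructureError",
    "UnknownTermError",
    "parse_obo",
    "ancestors",
    "information_content",
    "mica",
]

#: Allowed values for :attr:`Term.namespace`.
NAMESPACES = ("human-phenotype", "mammalian-phenotype", "shared")


class OntologyStructureError(ValueError):
    """The parsed graph violates a structural requirement (cycle, dangling id)."""


class UnknownTermError(KeyError):
    """A term id was looked up that is not present in the ontology."""


@dataclass(frozen=True)
class Term:
    """One ontology term: identifier, label, namespace and its direct parents."""

    id: str
    name: str
    namespace: str
    parents: tuple[str, ...]


def _infer_namespace(term_id: str, declared: str | None) -> str:
    if declared in NAMESPACES:
        return declared
    # Common OBO spellings map onto the three internal namespaces.
    if declared is not None:
        low = declared.lower().replace("_", "-")
        if "human" in low:
            return "human-phenotype"
        if "mammalian" in low or "mouse" in low:
            return "mammalian-phenotype"
    if term_id.startswith("HP:"):
        return "human-phenotype"
    if term_id.startswith("MP:"):
        return "mammalian-phenotype"
    return "shared"


class Ontology:
    """A rooted DAG of phenotype terms with memoised ancestor closure."""

    def __init__(self, terms: Mapping[str, Term]):
        self._terms: dict[str, Term] = dict(terms)
        # structural validation: parents resolve, graph acyclic
        graph = nx.DiGraph()
        graph.add_nodes_from(self._terms)
        for term in self._terms.values():
            for parent in term.parents:
                if parent not in self._terms:
                    raise OntologyStructureError(
                        f"term {term.id!r} has is_a target {parent!r} "
                        "which is not a term in the ontology"
                    )
                graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyStructureError(
                f"is_a structure contains a cycle through {cycle[0][0]!r}"
            )
        self._graph = graph
        self.roots: frozenset[str] = frozenset(
            t.id for t in self._terms.values() if not t.parents
        )
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- mapping-ish surface -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    @property
    def terms(self) -> Mapping[str, Term]:
        return self._terms

    def edges(self) -> Iterable[tuple[str, str]]:
        """Yield (child, parent) pairs for every is_a edge."""
        for term in self._terms.values():
            for parent in term.parents:
                yield term.id, parent

    # -- closure -------------------------------------------------------------
    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over parent edges.

        The returned set always contains ``term_id`` itself.
        """
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        # iterative DFS with memoisation; phenotype DAGs are shallow but this
        # avoids recursion-depth surprises on adversarial chains
        stack = [term_id]
        while stack:
            tid = stack[-1]
            if tid in self._anc_cache:
                stack.pop()
                continue
            pending = [p for p in self._terms[tid].parents if p not in self._anc_cache]
            if pending:
                stack.extend(pending)
                continue
            closure = {tid}
            for p in self._terms[tid].parents:
                closure |= self._anc_cache[p]
            self._anc_cache[tid] = frozenset(closure)
            stack.pop()
        return self._anc_cache[term_id]

    def descendants_root_check(self) -> None:
        """Assert every term reaches at least one root (true in any finite DAG)."""
        for tid in self._terms:
            if not (self.ancestors(tid) & self.roots):  # pragma: no cover
                raise OntologyStructureError(f"term {tid!r} reaches no root")


@dataclass
class ICTable:
    """Information content per term, in natural-log units.

    ``corpus_size`` is the number of annotated entities the table was
    computed from; IC values lie in ``[0, ln(corpus_size)]``.
    """

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)

    def to_tsv(self, path: str | Path) -> None:
        """Write a 2-column (term_id, ic) TSV for inspection."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term_id\tic\n")
            for tid in sorted(self.ic):
                fh.write(f"{tid}\t{self.ic[tid]:.10g}\n")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_obo(source: str | Path | io.TextIOBase) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Parameters
    ----------
    source
        A path to an ``.obo`` file, a text handle, or the OBO document itself
        as a string (detected by the presence of a newline).

    Only the ``id``, ``name``, ``namespace``, ``is_a`` and ``is_obsolete``
    tags are interpreted.  Obsolete terms are dropped entirely.  Relationship
    types other than ``is_a`` are ignored.

    Raises
    ------
    OntologyStructureError
        If an ``is_a`` target does not resolve to a term stanza, or the
        ``is_a`` graph contains a cycle (one member is named).
    """
    if isinstance(source, (io.TextIOBase,)):
        handle: io.TextIOBase = source
    elif isinstance(source, Path):
        handle = open(source, encoding="utf-8")
    elif isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(source, encoding="utf-8")

    with handle:
        # obonet warns on headers without name/ontology keys; irrelevant here
        logging.disable(logging.WARNING)
        try:
            graph = obonet.read_obo(handle, ignore_obsolete=True)
        finally:
            logging.disable(logging.NOTSET)

    # obonet adds bare nodes for edge targets that have no stanza of their
    # own; those carry an empty data dict, which is how we detect dangling
    # is_a references (including references to obsolete terms).
    stanza_ids = {n for n, data in graph.nodes(data=True) if data}
    terms: dict[str, Term] = {}
    for node in sorted(stanza_ids):
        data = graph.nodes[node]
        parents = tuple(
            sorted(
                target
                for _, target, key in graph.out_edges(node, keys=True)
                if key == "is_a"
            )
        )
        for parent in parents:
            if parent not in stanza_ids:
                raise OntologyStructureError(
                    f"term {node!r} has is_a target {parent!r} with no "
                    "[Term] stanza (dangling or obsolete reference)"
                )
        terms[node] = Term(
            id=node,
            name=str(data.get("name", node)),
            namespace=_infer_namespace(node, data.get("namespace")),
            parents=parents,
        )
    return Ontology(terms)


# ---------------------------------------------------------------------------
# functional op surface
# ---------------------------------------------------------------------------

def ancestors(ont: Ontology, term_id: str) -> frozenset[str]:
    """Reflexive ancestor set of ``term_id`` (see :meth:`Ontology.ancestors`)."""
    return ont.ancestors(term_id)


def information_content(
    ont: Ontology, corpus: Iterable[tuple[str, Iterable[str]]]
) -> ICTable:
    """Annotation-frequency information content over an annotated corpus.

    Parameters
    ----------
    ont
        The ontology whose terms are being annotated.
    corpus
        Iterable of ``(entity_id, term_ids)`` pairs; each entity counts once
        towards every annotated term and all of its ancestors.

    Returns
    -------
    ICTable
        ``IC(t) = -ln(count(t) / N)`` where ``count(t)`` is the number of
        distinct entities annotated to ``t`` or any descendant, ``N`` the
        corpus size.  Never-annotated terms get ``ln(N)``; roots get 0.
    """
    counts: Counter[str] = Counter()
    n_entities = 0
    for entity_id, term_ids in corpus:
        n_entities += 1
        cover: set[str] = set()
        for tid in term_ids:
            if tid not in ont:
                raise UnknownTermError(
                    f"entity {entity_id!r} is annotated to unknown term {tid!r}"
                )
            cover |= ont.ancestors(tid)
        counts.update(cover)
    if n_entities == 0:
        raise ValueError("IC corpus is empty")

    max_ic = math.log(n_entities)
    table: dict[str, float] = {}
    for tid in ont.terms:
        if tid in ont.roots:
            table[tid] = 0.0
            continue
        c = counts.get(tid, 0)
        table[tid] = max_ic if c == 0 else -math.log(c / n_entities)
    return ICTable(ic=table, corpus_size=n_entities)


def mica(
    ont: Ontology, ic: ICTable, t1: str, t2: str
) -> tuple[str | None, float]:
    """Most-informative common ancestor of two terms.

    Returns ``(term_id, ic_value)``.  Ties on IC are broken towards the
    lexicographically smallest term id, so the returned *value* is unique
    even when the term is not.  If the two terms share no ancestor (the
    graph is disconnected) the sentinel ``(None, 0.0)`` is returned.
    """
    common = ont.ancestors(t1) & ont.ancestors(t2)
    if not common:
        return None, 0.0
    best = min(common, key=lambda tid: (-ic[tid], tid))
    return best, ic[best]
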