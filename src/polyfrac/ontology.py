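"""Gene Ontology handling: OBO parsing, ancestor closure, set annotation.

Annotations attached to individual genes are lifted to whole homology sets:
a set is annotated with the union of its members' GO terms plus every
ancestor of those terms, with multiplicity ignored (presence/absence only).
"High-level terms" are the direct children of the three namespace roots
(biological_process, molecular_function, cellular_component); their exact
number varies with the ontology release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

__all__ = [
    "OntologyDAG",
    "OboFormatError",
    "load_ontology",
    "read_annotations",
    "annotate_sets",
    "annotate_genes",
    "write_set_annotations",
]


class OboFormatError(ValueError):
    pass


@dataclass
class OntologyDAG:
    """A parsed GO DAG restricted to the chosen propagation relations.

    ``parents`` holds the direct parent sets used for propagation (is_a, and
    optionally part_of restricted to same-namespace pairs so closure never
    crosses namespaces).  Obsolete terms are dropped at load time.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str]
    name: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via parent edges (term excluded)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def high_level_terms(self) -> set[str]:
        """Direct children of the namespace roots."""
        roots = self.roots()
        children: set[str] = set()
        for t in self.terms:
            if self.parents.get(t, set()) & roots:
                children.add(t)
        return children

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        """Terms plus all their ancestors (unknown terms ignored)."""
        out: set[str] = set()
        for t in terms:
            if t in self.terms:
                out.add(t)
                out |= self.ancestors(t)
        return frozenset(out)


def load_ontology(obo_source, include_part_of: bool = False) -> OntologyDAG:
    """Parse an OBO 1.2 file into an :class:`OntologyDAG`.

    Propagation uses ``is_a`` edges; ``include_part_of=True`` adds
    ``part_of`` edges between terms of the same namespace.  Obsolete terms
    are dropped and logged.  Raises :class:`OboFormatError` on cyclic edges
    or unknown namespaces.
    """
    graph = obonet.read_obo(obo_source, ignore_obsolete=False)
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    obsolete: set[str] = set()
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "false")).lower() == "true":
            obsolete.add(node)
            continue
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            raise OboFormatError(f"term {node}: unknown namespace {ns!r}")
        terms.add(node)
        namespace[node] = ns
        names[node] = data.get("name", "")
        parents[node] = set()
    # obonet edges run child -> parent, keyed by relation type
    check = nx.DiGraph()
    for child, parent, rel in graph.edges(keys=True):
        if child in obsolete or parent in obsolete or parent not in terms:
            continue
        if rel == "is_a" or (
            include_part_of
            and rel == "part_of"
            and namespace[child] == namespace[parent]
        ):
            parents[child].add(parent)
            check.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(check):
        raise OboFormatError("ontology contains a cycle")
    if obsolete:
        logger.info("dropped %d obsolete terms", len(obsolete))
    return OntologyDAG(
        terms=terms, parents=parents, namespace=namespace, name=names,
        obsolete=obsolete,
    )


def read_annotations(path, fmt: str = "auto", dag: Optional[OntologyDAG] = None) -> dict[str, set[str]]:
    """Read direct gene->GO annotations.

    Supports GAF 2.x (gene from column 2, term from column 5) and plain
    two-column TSV ``gene_id<TAB>term_id``.  ``fmt="auto"`` sniffs for the
    ``!gaf-version`` header.  When ``dag`` is given, terms missing from it
    (e.g. obsolete) are dropped with a logged count.
    """
    path = str(path)
    if fmt == "auto":
        with open(path) as fh:
            first = fh.readline()
        fmt = "gaf" if first.startswith("!") else "tsv"
    ann: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            cols = line.split("\t")
            if fmt == "gaf":
                gene, term = cols[1], cols[4]
            else:
                gene, term = cols[0], cols[1]
            if dag is not None and term not in dag:
                dropped += 1
                continue
            ann.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("dropped %d annotations with terms absent from the DAG", dropped)
    return ann


def annotate_genes(
    gene_ids: Iterable[str], ann: Mapping[str, set[str]], dag: OntologyDAG
) -> dict[str, frozenset[str]]:
    """Ancestor-closed per-gene annotations (genes with none map to empty)."""
    return {g: dag.closure(ann.get(g, ())) for g in gene_ids}


def annotate_sets(sets, ann: Mapping[str, set[str]], dag: OntologyDAG) -> dict[str, frozenset[str]]:
    """Lift gene annotations to homology sets, ancestor-closed, presence only.

    ``sets`` is an iterable of objects with ``set_id`` and ``gene_ids`` (as
    built by :mod:`polyfrac.homology`) or a mapping set_id -> gene id list.
    Annotated genes that belong to no set are ignored (count logged).
    """
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = [(s.set_id, s.gene_ids) for s in sets]
    out: dict[str, frozenset[str]] = {}
    seen_genes: set[str] = set()
    for set_id, gene_ids in items:
        direct: set[str] = set()
        for g in gene_ids:
            seen_genes.add(g)
            direct |= ann.get(g, set())
        out[set_id] = dag.closure(direct)
    orphans = sum(1 for g in ann if g not in seen_genes)
    if orphans:
        logger.info("%d annotated genes belong to no homology set", orphans)
    return out


def write_set_annotations(set_ann: Mapping[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tterm_id\n")
        for set_id in sorted(set_ann):
            for term in sorted(set_ann[set_id]):
                fh.write(f"{set_id}\t{term}\n")


def read_set_annotations(path) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            set_id, term = line.rstrip("\n").split("\t")
            out.setdefault(set_id, set()).add(term)
    return {k: frozenset(v) for k, v in out.items()}
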