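"""Homology sets: syntenic homolog grouping and fractionation scoring.

A homology set collects all genes, across and within genomes, that descend
from a single gene of the common ancestor before a whole-genome
multiplication.  Sets are formed as connected components of the graph whose
vertices are genes and whose edges are pairwise syntenic orthology (between
genomes) or paralogy (within a genome) calls, as produced by synteny-mapping
tools such as SynMap/DAGChainer.  Each set is then scored by *fractionation
score*: the number of genomes of the analysis group that retain more than one
copy of the gene.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Gene",
    "HomologyEdge",
    "GenomeGroup",
    "HomologySet",
    "Completeness",
    "InputConsistencyError",
    "build_homology_sets",
    "fractionation_score",
    "classify_completeness",
    "filter_missing_two_clade",
    "unplaced_genes",
    "read_gene_table",
    "read_edge_list",
    "write_set_members",
    "write_set_summary",
    "counts_from_sets",
]


class InputConsistencyError(ValueError):
    """An edge references a gene that is absent from the gene table."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    genome_id: str


@dataclass(frozen=True)
class HomologyEdge:
    """One pairwise homology call between two genes.

    ``relation`` is ``"ortholog"`` for cross-genome pairs and ``"paralog"``
    for within-genome pairs; ``block_id`` optionally records the synteny
    block supporting the call.
    """

    gene_a: str
    gene_b: str
    relation: str = "ortholog"
    block_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on gene {self.gene_a!r}")
        if self.relation not in ("ortholog", "paralog"):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class GenomeGroup:
    """An ordered list of genomes analysed together, optionally with clades.

    ``clades`` maps a clade name to a subset of the genomes; clade subsets
    must be disjoint.  Clades constrain which missing-two homology sets are
    admissible (one absentee per clade).
    """

    name: str
    genomes: tuple[str, ...]
    clades: Optional[Mapping[str, frozenset[str]]] = None

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("GenomeGroup needs at least one genome")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome_id in GenomeGroup")
        if self.clades is not None:
            object.__setattr__(
                self,
                "clades",
                {k: frozenset(v) for k, v in self.clades.items()},
            )
            seen: set[str] = set()
            for members in self.clades.values():
                if members & seen:
                    raise ValueError("clade subsets must be disjoint")
                seen |= members


#: completeness labels; missing_one/missing_two carry the absent genome(s)
@dataclass(frozen=True)
class Completeness:
    kind: str  # full | missing_one | missing_two | reject
    absent: tuple[str, ...] = ()

    def __str__(self) -> str:  # used in summary TSVs
        if self.absent:
            return f"{self.kind}({','.join(self.absent)})"
        return self.kind


@dataclass
class HomologySet:
    """One reconstructed ancestral (pre-multiplication) gene."""

    set_id: str
    members: tuple[Gene, ...]
    copy_counts: dict[str, int] = field(default_factory=dict)
    score: int = 0
    completeness: Completeness = field(default_factory=lambda: Completeness("reject"))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.members)


def build_homology_sets(
    edges: Iterable[HomologyEdge],
    genes: Iterable[Gene],
    group: GenomeGroup,
    max_copies_per_genome: Optional[int] = None,
) -> list[HomologySet]:
    """Group genes into homology sets as connected components of the edge graph.

    Genes with no incident edge are excluded (see :func:`unplaced_genes`).
    Components are ordered, and set_ids assigned, by their lexicographically
    smallest member gene_id so repeated runs are reproducible.

    ``max_copies_per_genome`` optionally drops sets in which any genome
    exceeds the cap (a crude guard against tandem-array contamination);
    default keeps everything.
    """
    gene_index = {g.gene_id: g for g in genes}
    graph = nx.Graph()
    for e in edges:
        for gid in (e.gene_a, e.gene_b):
            if gid not in gene_index:
                raise InputConsistencyError(
                    f"edge ({e.gene_a}, {e.gene_b}, {e.relation}) references "
                    f"unknown gene {gid!r}"
                )
        ga, gb = gene_index[e.gene_a], gene_index[e.gene_b]
        same = ga.genome_id == gb.genome_id
        if e.relation == "ortholog" and same:
            raise InputConsistencyError(
                f"ortholog edge ({e.gene_a}, {e.gene_b}) joins two genes of "
                f"genome {ga.genome_id!r}"
            )
        if e.relation == "paralog" and not same:
            raise InputConsistencyError(
                f"paralog edge ({e.gene_a}, {e.gene_b}) spans genomes "
                f"{ga.genome_id!r} and {gb.genome_id!r}"
            )
        graph.add_edge(e.gene_a, e.gene_b)

    components = sorted(nx.connected_components(graph), key=min)
    sets: list[HomologySet] = []
    width = max(4, len(str(len(components))))
    for idx, comp in enumerate(components):
        members = tuple(gene_index[gid] for gid in sorted(comp))
        counts = Counter(g.genome_id for g in members)
        copy_counts = {g: counts.get(g, 0) for g in group.genomes}
        if max_copies_per_genome is not None and any(
            c > max_copies_per_genome for c in copy_counts.values()
        ):
            continue
        s = HomologySet(set_id=f"HS{idx:0{width}d}", members=members)
        s.copy_counts = copy_counts
        s.score = fractionation_score(s, group)
        s.completeness = classify_completeness(s, group)
        sets.append(s)
    return sets


def fractionation_score(s: HomologySet, group: GenomeGroup) -> int:
    """Number of genomes of the group holding more than one copy (2, 3, ...)."""
    return sum(1 for g in group.genomes if s.copy_counts.get(g, 0) > 1)


def classify_completeness(s: HomologySet, group: GenomeGroup) -> Completeness:
    """Label a set full / missing_one / missing_two / reject by absent genomes."""
    absent = tuple(g for g in group.genomes if s.copy_counts.get(g, 0) == 0)
    if not absent:
        return Completeness("full")
    if len(absent) == 1:
        return Completeness("missing_one", absent)
    if len(absent) == 2:
        return Completeness("missing_two", absent)
    return Completeness("reject", absent)


def filter_missing_two_clade(
    sets: Iterable[HomologySet], group: GenomeGroup
) -> list[HomologySet]:
    """Keep missing-two sets whose two absentees fall in different clades.

    Mirrors the four-genome grass analysis in which admissible sets lack one
    Panicoideae genome (sorghum or foxtail millet) and one BEP-clade genome
    (rice or Brachypodium).
    """
    if not group.clades or len(group.clades) != 2:
        raise ValueError("group must define exactly two clades")
    clade_of: dict[str, str] = {}
    for name, members in group.clades.items():
        for g in members:
            clade_of[g] = name
    kept = []
    for s in sets:
        if s.completeness.kind != "missing_two":
            continue
        a, b = s.completeness.absent
        if a in clade_of and b in clade_of and clade_of[a] != clade_of[b]:
            kept.append(s)
    return kept


def unplaced_genes(genes: Iterable[Gene], sets: Iterable[HomologySet]) -> list[Gene]:
    """Genes from the table that ended up in no homology set (no edges)."""
    placed = {gid for s in sets for gid in s.gene_ids}
    return [g for g in genes if g.gene_id not in placed]


def counts_from_sets(
    sets: Iterable[HomologySet],
    group: GenomeGroup,
    restrict: str = "full",
) -> pd.DataFrame:
    """Tally per-genome pair (n2) and triple (n3) counts from homology sets.

    ``restrict="full"`` counts only complete sets (every genome represented),
    mirroring the stable-genome framing; ``restrict="any"`` counts every set.
    A genome contributes a pair when it holds exactly 2 copies and a triple
    when it holds 3 or more.
    """
    if restrict not in ("full", "any"):
        raise ValueError("restrict must be 'full' or 'any'")
    rows = []
    pool = [
        s for s in sets if restrict == "any" or s.completeness.kind == "full"
    ]
    for g in group.genomes:
        n2 = sum(1 for s in pool if s.copy_counts.get(g, 0) == 2)
        n3 = sum(1 for s in pool if s.copy_counts.get(g, 0) >= 3)
        rows.append((g, n2, n3))
    return pd.DataFrame(rows, columns=["species", "n2", "n3"])


# ---------------------------------------------------------------------------
# TSV interfaces


def read_gene_table(path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "genome_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    return [Gene(r.gene_id, r.genome_id) for r in df.itertuples()]


def read_edge_list(path) -> list[HomologyEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_a", "gene_b", "relation"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list lacks columns: {sorted(missing)}")
    has_block = "block_id" in df.columns
    out = []
    for r in df.itertuples():
        block = getattr(r, "block_id", None) if has_block else None
        if block in (".", "", None) or pd.isna(block):
            block = None
        out.append(HomologyEdge(r.gene_a, r.gene_b, r.relation, block))
    return out


def write_set_members(sets: Sequence[HomologySet], path) -> None:
    rows = [
        (s.set_id, g.genome_id, g.gene_id) for s in sets for g in s.members
    ]
    pd.DataFrame(rows, columns=["set_id", "genome_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_set_summary(sets: Sequence[HomologySet], group: GenomeGroup, path) -> None:
    rows = []
    for s in sets:
        row: dict[str, object] = {"set_id": s.set_id}
        for g in group.genomes:
            row[f"copies_{g}"] = s.copy_counts.get(g, 0)
        row["score"] = s.score
        row["completeness"] = str(s.completeness)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_set_members(path, genes: Optional[Iterable[Gene]] = None) -> dict[str, tuple[Gene, ...]]:
    """Reload a set-membership TSV into set_id -> member genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[Gene]] = {}
    for r in df.itertuples():
        out.setdefault(r.set_id, []).append(Gene(r.gene_id, r.genome_id))
    return {k: tuple(v) for k, v in out.items()}
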