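"""Synthetic triplication/fractionation data with known ground truth.

The generator reproduces the statistical structure the analysis assumes so
every pipeline stage can be exercised without external genome downloads:

* N ancestral genes are split into two rate classes (proportion ``theta``
  fast, ``1-theta`` slow, rates linked by ``alpha``);
* each gene is triplicated; each copy survives a single shared
  pre-speciation phase with probability 1-p (one draw per copy, seen by all
  descendant species), then survives independently in each species with
  probability 1-q_i;
* surviving copies of one ancestral gene are connected by ortholog edges
  across genomes and paralog edges within genomes, so homology-set
  reconstruction should recover the simulated sets exactly;
* a toy three-root ontology is generated and leaf terms are assigned to
  genes with class-dependent inclusion probabilities, planting
  fractionation-prone/resistant categories.

Deliberately absent from the default generator: gene movement, tandem
duplication and annotation noise (an optional ``annotation_noise`` rate adds
uniform false assignments for robustness experiments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .homology import Gene, GenomeGroup, HomologyEdge
from .retention import RetentionParams

__all__ = [
    "ToyOntologySpec",
    "SimConfig",
    "SimResult",
    "simulate_fractionation",
    "make_toy_obo",
    "assign_annotations",
    "write_fixtures",
]


@dataclass(frozen=True)
class ToyOntologySpec:
    """Shape of the generated toy ontology: 3 roots, regular tree below."""

    depth: int = 2
    branching: int = 3

    def term_ids(self) -> dict[str, list[str]]:
        """Deterministic term ids per namespace level (leaf level last)."""
        out = {}
        counter = 1
        for ns_idx in range(3):
            levels = []
            n = 1
            for level in range(self.depth + 1):
                ids = [f"GO:{counter + k:07d}" for k in range(n)]
                counter += n
                levels.append(ids)
                n *= self.branching
            out[f"ns{ns_idx}"] = levels
        return out


@dataclass(frozen=True)
class SimConfig:
    params: RetentionParams
    group: GenomeGroup
    ontology: ToyOntologySpec = field(default_factory=ToyOntologySpec)
    #: term_id -> (inclusion prob in fast/prone class, in slow/resistant class)
    term_bias: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    annotation_noise: float = 0.0
    #: draw phase-1 survival independently per species instead of shared
    #: (matches the likelihood's independence idealisation exactly)
    independent_phase1: bool = False
    #: skip gene/edge emission for count-level studies (much faster)
    emit_edges: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group.genomes) != self.params.n_species:
            raise ValueError("group size must match the number of q_i rates")
        for term, (b1, b2) in self.term_bias.items():
            if not (0 <= b1 <= 1 and 0 <= b2 <= 1):
                raise ValueError(f"term_bias for {term} outside [0, 1]")


@dataclass
class SimResult:
    config: SimConfig
    #: per ancestral gene: True = fast (fractionation-prone) class
    gene_class: np.ndarray
    #: (N, S) surviving copy counts per species
    copy_counts: np.ndarray
    genes: list[Gene]
    edges: list[HomologyEdge]
    #: ancestral index for every emitted gene (parallel with ``genes``)
    gene_ancestor: list[int]
    counts: pd.DataFrame  # realized per-species n2/n3 (Table-1 shape)

    @property
    def n_ancestral(self) -> int:
        return len(self.gene_class)

    def true_sets(self) -> dict[int, set[str]]:
        """Ancestral gene index -> emitted gene ids (sets with >=2 genes)."""
        out: dict[int, set[str]] = {}
        for g, anc in zip(self.genes, self.gene_ancestor):
            out.setdefault(anc, set()).add(g.gene_id)
        return {k: v for k, v in out.items() if len(v) >= 2}

    def score_by_class(self) -> pd.DataFrame:
        """Realized fractionation-score distribution per class."""
        scores = (self.copy_counts > 1).sum(axis=1)
        rows = []
        for label, mask in (
            ("prone", self.gene_class),
            ("resistant", ~self.gene_class),
        ):
            for k in range(len(self.config.group.genomes) + 1):
                rows.append(
                    {
                        "class": label,
                        "score": k,
                        "genes": int(((scores == k) & mask).sum()),
                    }
                )
        return pd.DataFrame(rows)


def simulate_fractionation(config: SimConfig) -> SimResult:
    """Run the two-phase loss process and emit genes, edges and counts."""
    rng = np.random.default_rng(config.seed)
    par = config.params
    N, S = par.n_ancestral, par.n_species
    genomes = config.group.genomes

    is_fast = rng.random(N) < par.theta
    p_eff = np.where(is_fast, par.p, par.alpha * par.p)
    q_eff = np.empty((N, S))
    for i in range(S):
        q_eff[:, i] = np.where(is_fast, par.q[i], par.alpha * par.q[i])

    if config.independent_phase1:
        # phase 1 re-drawn per species: per-copy survival is iid (1-p)(1-q)
        surv = np.empty((N, 3, S), dtype=bool)
        for i in range(S):
            s1 = rng.random((N, 3)) < (1 - p_eff)[:, None]
            s2 = rng.random((N, 3)) < (1 - q_eff[:, i])[:, None]
            surv[:, :, i] = s1 & s2
    else:
        shared1 = rng.random((N, 3)) < (1 - p_eff)[:, None]
        surv = np.empty((N, 3, S), dtype=bool)
        for i in range(S):
            s2 = rng.random((N, 3)) < (1 - q_eff[:, i])[:, None]
            surv[:, :, i] = shared1 & s2

    copy_counts = surv.sum(axis=1)  # (N, S)

    genes: list[Gene] = []
    gene_ancestor: list[int] = []
    edges: list[HomologyEdge] = []
    for anc in range(N) if config.emit_edges else ():
        present: list[Gene] = []
        for i, genome in enumerate(genomes):
            for c in range(3):
                if surv[anc, c, i]:
                    g = Gene(f"g{anc:06d}_{genome}_c{c}", genome)
                    present.append(g)
        genes.extend(present)
        gene_ancestor.extend([anc] * len(present))
        for a_idx in range(len(present)):
            for b_idx in range(a_idx + 1, len(present)):
                ga, gb = present[a_idx], present[b_idx]
                rel = "paralog" if ga.genome_id == gb.genome_id else "ortholog"
                edges.append(HomologyEdge(ga.gene_id, gb.gene_id, rel, None))

    counts = pd.DataFrame(
        {
            "species": list(genomes),
            "n2": (copy_counts == 2).sum(axis=0),
            "n3": (copy_counts == 3).sum(axis=0),
        }
    )
    return SimResult(
        config=config,
        gene_class=is_fast,
        copy_counts=copy_counts,
        genes=genes,
        edges=edges,
        gene_ancestor=gene_ancestor,
        counts=counts,
    )


def make_toy_obo(spec: ToyOntologySpec) -> str:
    """Render the toy three-namespace ontology as OBO 1.2 text."""
    ns_names = ["biological_process", "molecular_function", "cellular_component"]
    ids = spec.term_ids()
    lines = ["format-version: 1.2", "ontology: polyfrac-toy", ""]
    for ns_key, ns_name in zip(ids, ns_names):
        levels = ids[ns_key]
        for level, terms in enumerate(levels):
            for j, term in enumerate(terms):
                lines += ["[Term]", f"id: {term}"]
                if level == 0:
                    lines.append(f"name: {ns_name}")
                else:
                    lines.append(f"name: {ns_name} L{level} T{j}")
                lines.append(f"namespace: {ns_name}")
                if level > 0:
                    parent = levels[level - 1][j // spec.branching]
                    lines.append(f"is_a: {parent}")
                lines.append("")
    return "\n".join(lines)


def toy_leaf_terms(spec: ToyOntologySpec) -> list[str]:
    """Leaf term ids of the toy ontology, all namespaces, in id order."""
    ids = spec.term_ids()
    leaves: list[str] = []
    for ns_key in ids:
        leaves.extend(ids[ns_key][-1])
    return sorted(leaves)


def assign_annotations(sim: SimResult, config: Optional[SimConfig] = None) -> dict[str, set[str]]:
    """Assign biased leaf terms to surviving genes, class-dependently.

    Every gene of an ancestral gene draws each biased term once per set
    (i.e. the ancestral gene decides, and all its descendants share the
    annotation), so set-level presence probabilities equal the configured
    bias exactly.  Ancestor closure is left to the ontology module.
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 1)
    leaves = set(toy_leaf_terms(config.ontology))
    for term in config.term_bias:
        if term not in leaves:
            raise ValueError(f"term_bias references non-leaf term {term}")
    N = sim.n_ancestral
    anc_terms: dict[int, set[str]] = {a: set() for a in range(N)}
    for term, (b_fast, b_slow) in sorted(config.term_bias.items()):
        prob = np.where(sim.gene_class, b_fast, b_slow)
        take = rng.random(N) < prob
        for anc in np.nonzero(take)[0]:
            anc_terms[int(anc)].add(term)
    ann: dict[str, set[str]] = {}
    for g, anc in zip(sim.genes, sim.gene_ancestor):
        terms = set(anc_terms[anc])
        if config.annotation_noise > 0:
            for term in sorted(leaves):
                if rng.random() < config.annotation_noise:
                    terms.add(term)
        if terms:
            ann[g.gene_id] = terms
    return ann


def write_fixtures(
    sim: SimResult,
    out_dir,
    annotations: Optional[Mapping[str, set[str]]] = None,
) -> dict[str, dict]:
    """Write all pipeline input files plus ground truth; return a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    genes_df = pd.DataFrame(
        [(g.gene_id, g.genome_id) for g in sim.genes],
        columns=["gene_id", "genome_id"],
    )
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    manifest["genes.tsv"] = {"rows": len(genes_df)}

    edges_df = pd.DataFrame(
        [(e.gene_a, e.gene_b, e.relation, e.block_id or ".") for e in sim.edges],
        columns=["gene_a", "gene_b", "relation", "block_id"],
    )
    edges_df.to_csv(out / "edges.tsv", sep="\t", index=False)
    manifest["edges.tsv"] = {"rows": len(edges_df)}

    obo_text = make_toy_obo(sim.config.ontology)
    (out / "ontology.obo").write_text(obo_text)
    manifest["ontology.obo"] = {"terms": obo_text.count("[Term]")}

    if annotations is None:
        annotations = assign_annotations(sim)
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        n_rows = 0
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
                n_rows += 1
    manifest["annotations.tsv"] = {"rows": n_rows}

    sim.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    manifest["counts.tsv"] = {"rows": len(sim.counts)}

    truth = {
        "seed": sim.config.seed,
        "n_ancestral": sim.n_ancestral,
        "theta": sim.config.params.theta,
        "alpha": sim.config.params.alpha,
        "p": sim.config.params.p,
        "q": list(sim.config.params.q),
        "realized_counts": sim.counts.to_dict(orient="list"),
        "n_fast_class": int(sim.gene_class.sum()),
        "score_by_class": sim.score_by_class().to_dict(orient="list"),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    manifest["ground_truth.json"] = {"keys": len(truth)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
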