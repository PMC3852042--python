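import numpy as np
import pytest

from polyfrac.homology import Gene, GenomeGroup, HomologyEdge
from polyfrac.ontology import load_ontology
from polyfrac.simulate import ToyOntologySpec, make_toy_obo


@pytest.fixture(scope="session")
def toy_dag(tmp_path_factory):
    """Three namespaces, two levels below each root, branching 3 (39 terms)."""
    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    path.write_text(make_toy_obo(ToyOntologySpec(depth=2, branching=3)))
    return load_ontology(str(path))


@pytest.fixture
def three_genome_group():
    return GenomeGroup("rosids", ("peach", "cacao", "grape"))


def random_homology_instance(seed, n_genes=50, n_edges=60, n_genomes=3):
    """Random valid gene/edge instance for component-oracle comparisons."""
    rng = np.random.default_rng(seed)
    genomes = [f"G{i}" for i in range(n_genomes)]
    genes = [Gene(f"g{i:03d}", genomes[rng.integers(n_genomes)]) for i in range(n_genes)]
    by_id = {g.gene_id: g for g in genes}
    edges = []
    while len(edges) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        ga, gb = genes[a], genes[b]
        rel = "paralog" if ga.genome_id == gb.genome_id else "ortholog"
        edges.append(HomologyEdge(ga.gene_id, gb.gene_id, rel))
    group = GenomeGroup("random", tuple(genomes))
    return genes, edges, group


def merge_closure_oracle(edges):
    """Brute-force transitive closure: merge overlapping pairs to fixpoint."""
    sets = [{e.gene_a, e.gene_b} for e in edges]
    changed = True
    while changed:
        changed = False
        out = []
        while sets:
            cur = sets.pop()
            merged = True
            while merged:
                merged = False
                for other in list(sets):
                    if cur & other:
                        cur |= other
                        sets.remove(other)
                        merged = True
                        changed = True
            out.append(cur)
        sets = out
    return {frozenset(s) for s in sets}
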