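"""Brute-force oracles for ortholog-cluster tests.

These deliberately avoid the code paths they check: triangles are found by
exhaustive triple enumeration, seed expansion by explicit graph
reachability over independently recomputed best-hit edges.
"""

import itertools

import networkx as nx
import numpy as np

from orthosel.cogfinder import BeTGraph, HitTable, collapse_paralogs


def random_hit_table(rng, n_genomes=3, genes_per_genome=4, p_hit=0.6) -> HitTable:
    genome_of = {
        f"g{g}x{k}": f"g{g}"
        for g in range(n_genomes)
        for k in range(genes_per_genome)
    }
    scores = {}
    for a, b in itertools.combinations(sorted(genome_of), 2):
        if rng.random() < p_hit:
            s = float(rng.integers(10, 200))
            scores[(a, b)] = scores[(b, a)] = s
    return HitTable(scores=scores, genome_of=genome_of)


def random_bet_graph(rng, max_nodes=20) -> BeTGraph:
    n_genomes = int(rng.integers(3, 6))
    n_nodes = int(rng.integers(6, max_nodes + 1))
    genome_of = {f"n{i}": f"g{rng.integers(n_genomes)}" for i in range(n_nodes)}
    edges = []
    names = sorted(genome_of)
    for a, b in itertools.combinations(names, 2):
        if genome_of[a] != genome_of[b] and rng.random() < 0.3:
            kind = "symmetric" if rng.random() < 0.6 else "asymmetric"
            edges.append((a, b, kind))
    return BeTGraph(nodes=set(names), genome_of=genome_of, edges=edges)


def triangle_merge_oracle(bets: BeTGraph) -> set[frozenset]:
    """All 3-genome triangles by exhaustive enumeration, merged on shared edges."""
    adj = bets.undirected()
    g = nx.Graph()
    for a, b, c in itertools.combinations(sorted(adj.nodes), 3):
        if (
            adj.has_edge(a, b) and adj.has_edge(a, c) and adj.has_edge(b, c)
            and len({bets.genome_of[x] for x in (a, b, c)}) == 3
        ):
            g.add_edges_from([(a, b), (a, c), (b, c)])
    return {frozenset(comp) for comp in nx.connected_components(g)}


def expansion_oracle(seed_gene: str, hits: HitTable) -> set[str]:
    """Reachability over per-(gene, genome) argmax edges plus paralog groups."""
    g = nx.DiGraph()
    g.add_nodes_from(hits.genome_of)
    genomes = sorted(set(hits.genome_of.values()))
    for gene in hits.genome_of:
        for genome in genomes:
            if genome == hits.genome_of[gene]:
                continue
            cands = [
                x for x in hits.genome_of
                if hits.genome_of[x] == genome and np.isfinite(hits.score(gene, x))
            ]
            if cands:
                top = max(hits.score(gene, x) for x in cands)
                best = min(x for x in cands if hits.score(gene, x) == top)
                g.add_edge(gene, best)
    for genome in genomes:
        genes = [x for x, gn in hits.genome_of.items() if gn == genome]
        for group in collapse_paralogs(hits, genes):
            for a, b in itertools.combinations(sorted(group), 2):
                g.add_edge(a, b)
                g.add_edge(b, a)
    return {seed_gene} | nx.descendants(g, seed_gene)
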