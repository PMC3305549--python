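"""Ortholog family detection by reciprocal best hits (the COG procedure).

Orthologous groups are recovered from the notion that genes from distant
genomes belonging to one family are more similar to each other than to any
other gene of the same genomes.  The stages:

1. all-against-all local protein alignment scores (Smith–Waterman via
   Bio.Align, BLOSUM62, affine gaps; only score *rankings* matter, so no
   bit-score calibration is applied);
2. per-(gene, genome) best hits (BeTs), classified symmetric when
   reciprocal;
3. collapsing of obvious within-genome paralogs (mutual within-genome
   dominance over every cross-genome score);
4. iterative seed expansion to closure over BeT edges;
5. cluster formation: BeT edges participating in a three-genome triangle,
   triangles merged on shared edges (the Tatusov rule), clusters as the
   connected components of the retained edges.

Clusters come with a per-cluster diagnostic table (genome coverage, score
range) in lieu of manual case-by-case curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import GenomeSet

__all__ = [
    "Scoring",
    "HitTable",
    "BeTGraph",
    "COGCluster",
    "all_against_all",
    "best_hits",
    "collapse_paralogs",
    "expand_from_seed",
    "form_cogs",
    "export_network",
    "read_network",
    "background_min_score",
    "cluster_table",
]


@dataclass
class Scoring:
    """Local-alignment scoring: substitution matrix plus affine gap costs."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def aligner(self) -> Align.PairwiseAligner:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


@dataclass
class HitTable:
    """Directed (query, subject) similarity scores plus the gene→genome map.

    :func:`all_against_all` stores both directions of every retained pair
    (the local-alignment score is symmetric); hand-built tables may be
    directed, in which case best hits are computed from each query's own
    entries, mirroring a one-sided search report.
    """

    scores: dict[tuple[str, str], float]
    genome_of: dict[str, str]

    def score(self, a: str, b: str) -> float:
        """Score of the pair in either direction; -inf when absent."""
        return self.scores.get((a, b), self.scores.get((b, a), -np.inf))

    def genes(self) -> list[str]:
        return sorted(self.genome_of)

    def cross_genome_max(self, gene: str) -> float:
        """Best score of ``gene`` against any gene of any other genome."""
        g = self.genome_of[gene]
        best = -np.inf
        for (a, b), s in self.scores.items():
            if a == gene and self.genome_of[b] != g:
                best = max(best, s)
            elif b == gene and self.genome_of[a] != g:
                best = max(best, s)
        return best


@dataclass
class BeTGraph:
    """Best-hit network: edges (a, b) classified symmetric/asymmetric."""

    nodes: set[str]
    genome_of: dict[str, str]
    edges: list[tuple[str, str, str]]  # (a, b, "symmetric"|"asymmetric")

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, kind in self.edges:
            # symmetric overrides asymmetric if both recorded
            if g.has_edge(a, b) and g.edges[a, b]["kind"] == "symmetric":
                continue
            g.add_edge(a, b, kind=kind)
        return g


@dataclass
class COGCluster:
    cluster_id: str
    members: list[str]
    edges: list[tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------


def all_against_all(
    genomes: GenomeSet,
    scoring: Scoring | None = None,
    min_score: float = 0.0,
) -> HitTable:
    """Score every gene pair (within and across genomes) above ``min_score``.

    Smith–Waterman local alignment scores are symmetric, so each unordered
    pair is computed once; self-hits are dropped.
    """
    if len(genomes.genomes) < 2:
        raise ValueError("need at least two genomes")
    for g in genomes.genomes.values():
        if not g.genes:
            raise ValueError(f"empty genome {g.genome_id!r}")
    scoring = scoring or Scoring()
    aligner = scoring.aligner()
    genome_of = genomes.gene_to_genome()
    seqs = {gid: genomes.record(gid).protein for gid in genome_of}
    scores: dict[tuple[str, str], float] = {}
    gene_ids = sorted(genome_of)
    for a, b in combinations(gene_ids, 2):
        s = float(aligner.score(seqs[a], seqs[b]))
        if s >= min_score:
            scores[(a, b)] = s
            scores[(b, a)] = s
    return HitTable(scores=scores, genome_of=genome_of)


def background_min_score(
    genomes: GenomeSet,
    scoring: Scoring | None = None,
    *,
    quantile: float = 0.99,
    n_pairs: int = 200,
    seed: int = 0,
) -> float:
    """Similarity threshold from a shuffled-sequence background distribution.

    Scores ``n_pairs`` pairs of residue-shuffled proteins drawn from the
    genome set and returns the requested quantile — an internal stand-in
    for an E-value cutoff that needs no external statistics.
    """
    scoring = scoring or Scoring()
    aligner = scoring.aligner()
    rng = np.random.default_rng(seed)
    proteins = [genomes.record(g).protein for g in sorted(genomes.gene_to_genome())]
    vals = []
    for _ in range(n_pairs):
        pa, pb = rng.choice(len(proteins), size=2, replace=True)
        a = "".join(rng.permutation(list(proteins[pa])))
        b = "".join(rng.permutation(list(proteins[pb])))
        vals.append(float(aligner.score(a, b)))
    return float(np.quantile(vals, quantile))


def _bets_of(gene: str, hits: HitTable) -> dict[str, str]:
    """Best hit of ``gene`` in every other genome (ties: lexicographic).

    Only entries with ``gene`` as the query are considered.
    """
    g = hits.genome_of[gene]
    best: dict[str, tuple[float, str]] = {}
    for (a, b), s in hits.scores.items():
        if a != gene:
            continue
        other = b
        og = hits.genome_of[other]
        if og == g:
            continue
        cur = best.get(og)
        if cur is None or s > cur[0] or (s == cur[0] and other < cur[1]):
            best[og] = (s, other)
    return {og: gene_ for og, (_, gene_) in best.items()}


def best_hits(hits: HitTable) -> BeTGraph:
    """Compute the BeT network over all genes in the hit table.

    An edge (a, b) is symmetric iff a is b's best hit in a's genome and
    vice versa; a one-directional best hit yields an asymmetric edge.
    """
    if not hits.genome_of:
        raise ValueError("empty hit table")
    bets = {gene: _bets_of(gene, hits) for gene in hits.genome_of}
    edges: dict[tuple[str, str], str] = {}
    for gene, per_genome in bets.items():
        for target in per_genome.values():
            key = (min(gene, target), max(gene, target))
            reciprocal = bets[target].get(hits.genome_of[gene]) == gene
            kind = "symmetric" if reciprocal else "asymmetric"
            if edges.get(key) != "symmetric":
                edges[key] = kind
    return BeTGraph(
        nodes=set(hits.genome_of),
        genome_of=dict(hits.genome_of),
        edges=sorted((a, b, k) for (a, b), k in edges.items()),
    )


def collapse_paralogs(hits: HitTable, genes: list[str]) -> list[set[str]]:
    """Partition same-genome genes into obvious-paralog groups.

    Two genes join when they score higher with each other than either does
    with any gene of any other genome (mutual within-genome dominance);
    groups are the connected components of that relation.
    """
    if not genes:
        return []
    genomes = {hits.genome_of[g] for g in genes}
    if len(genomes) != 1:
        raise ValueError("collapse_paralogs expects genes from one genome")
    g = nx.Graph()
    g.add_nodes_from(genes)
    cross_max = {x: hits.cross_genome_max(x) for x in genes}
    for a, b in combinations(sorted(genes), 2):
        s = hits.score(a, b)
        if s > cross_max[a] and s > cross_max[b]:
            g.add_edge(a, b)
    return sorted(
        (set(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )


def paralog_representative(group: set[str], hits: HitTable) -> str:
    """Highest-scoring member of a collapsed group (ties: lexicographic)."""
    return max(sorted(group), key=lambda g: hits.cross_genome_max(g))


def expand_from_seed(seed_gene: str, hits: HitTable) -> set[str]:
    """Closure of {seed} under "add all BeTs of members and their paralogs".

    Monotone and bounded by the gene universe, so iteration terminates at a
    fixed point.
    """
    if seed_gene not in hits.genome_of:
        raise KeyError(f"seed gene {seed_gene!r} not in hit table")
    members = {seed_gene}
    while True:
        new = set()
        for gene in members:
            # collapsed paralogs of this gene within its genome
            genome = hits.genome_of[gene]
            same_genome = [x for x in hits.genome_of if hits.genome_of[x] == genome]
            for group in collapse_paralogs(hits, same_genome):
                if gene in group:
                    new |= group
            new |= set(_bets_of(gene, hits).values())
        new -= members
        if not new:
            return members
        members |= new


def form_cogs(bets: BeTGraph) -> list[COGCluster]:
    """Clusters from BeT triangles spanning three genomes, merged on edges.

    Only edges participating in at least one triangle whose three genes
    come from three distinct genomes are retained; clusters are the
    connected components of the retained edge set.  Output order and
    cluster ids are deterministic (sorted by smallest member).
    """
    g = bets.undirected()
    keep = nx.Graph()
    for tri in _triangles(g):
        a, b, c = tri
        if len({bets.genome_of[a], bets.genome_of[b], bets.genome_of[c]}) == 3:
            for x, y in ((a, b), (a, c), (b, c)):
                keep.add_edge(x, y, kind=g.edges[x, y]["kind"])
    clusters = []
    comps = sorted(nx.connected_components(keep), key=lambda c: min(c))
    for i, comp in enumerate(comps):
        members = sorted(comp)
        edges = sorted(
            (min(a, b), max(a, b), d["kind"])
            for a, b, d in keep.subgraph(comp).edges(data=True)
        )
        clusters.append(COGCluster(cluster_id=f"COG{i:04d}", members=members, edges=edges))
    return clusters


def _triangles(g: nx.Graph):
    for a in sorted(g.nodes):
        nbrs = sorted(n for n in g.neighbors(a) if n > a)
        for i, b in enumerate(nbrs):
            for c in nbrs[i + 1 :]:
                if g.has_edge(b, c):
                    yield (a, b, c)


def cluster_table(clusters: list[COGCluster], hits: HitTable):
    """Per-cluster diagnostics: genome coverage and within-cluster score range."""
    import pandas as pd

    rows = []
    for cl in clusters:
        scores = [
            hits.score(a, b) for a, b in combinations(cl.members, 2)
            if np.isfinite(hits.score(a, b))
        ]
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "n_members": len(cl.members),
                "n_genomes": len({hits.genome_of[m] for m in cl.members}),
                "min_score": min(scores) if scores else np.nan,
                "max_score": max(scores) if scores else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network export


def export_network(cluster: COGCluster, out: str | Path) -> None:
    """Write the cluster's BeT subgraph as GraphML plus an edge-list TSV."""
    g = nx.Graph()
    g.add_nodes_from(cluster.members)
    for a, b, kind in cluster.edges:
        g.add_edge(a, b, kind=kind)
    out = Path(out)
    nx.write_graphml(g, out.with_suffix(".graphml"))
    with open(out.with_suffix(".tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tkind\n")
        for a, b, kind in cluster.edges:
            fh.write(f"{a}\t{b}\t{kind}\n")


def read_network(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back an edge-list TSV written by :func:`export_network`."""
    edges = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, kind = line.rstrip("\n").split("\t")
            edges.append((min(a, b), max(a, b), kind))
    return sorted(edges)
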