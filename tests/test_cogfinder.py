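import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthosel import cogfinder
from orthosel.cogfinder import (
    BeTGraph,
    HitTable,
    Scoring,
    all_against_all,
    best_hits,
    collapse_paralogs,
    expand_from_seed,
    form_cogs,
)


def random_hit_table(rng, n_genomes=3, genes_per_genome=4, p_hit=0.7):
    genome_of = {}
    for g in range(n_genomes):
        for k in range(genes_per_genome):
            genome_of[f"g{g}x{k}"] = f"g{g}"
    scores = {}
    genes = sorted(genome_of)
    for a, b in itertools.combinations(genes, 2):
        if rng.random() < p_hit:
            s = float(rng.integers(10, 200))
            scores[(a, b)] = scores[(b, a)] = s
    return HitTable(scores=scores, genome_of=genome_of)


class TestAllAgainstAll:
    def test_self_alignment_score_equals_diagonal_sum(self, small_genomes):
        genomes, _ = small_genomes
        gene = next(iter(next(iter(genomes.genomes.values())).genes.values()))
        blosum = substitution_matrices.load("BLOSUM62")
        expected = sum(blosum[aa, aa] for aa in gene.protein)
        aligner = Scoring().aligner()
        assert aligner.score(gene.protein, gene.protein) == pytest.approx(expected)

    def test_scores_symmetric_and_thresholded(self, small_genomes):
        genomes, _ = small_genomes
        hits = all_against_all(genomes, min_score=60.0)
        aligner = Scoring().aligner()
        assert all(s >= 60.0 for s in hits.scores.values())
        rng = np.random.default_rng(0)
        pairs = list(hits.scores)
        for a, b in [pairs[i] for i in rng.choice(len(pairs), 10, replace=False)]:
            pa, pb = genomes.record(a).protein, genomes.record(b).protein
            assert aligner.score(pa, pb) == aligner.score(pb, pa) == hits.scores[(a, b)]

    def test_unrelated_pairs_fall_below_background_threshold(self, small_genomes):
        genomes, truths = small_genomes
        threshold = cogfinder.background_min_score(genomes, seed=1)
        hits = all_against_all(genomes, min_score=threshold)
        fam = {m for _, m in truths[0].members}
        other = {m for _, m in truths[1].members}
        for a in fam:
            for b in other:
                assert not np.isfinite(hits.score(a, b))

    def test_empty_genome_rejected(self, small_genomes):
        import copy

        genomes, _ = small_genomes
        broken = copy.deepcopy(genomes)
        next(iter(broken.genomes.values())).genes.clear()
        with pytest.raises(ValueError, match="empty genome"):
            all_against_all(broken)


class TestBestHits:
    def test_reciprocal_top_hit_is_symmetric(self):
        hits = HitTable(
            scores={("a1", "b1"): 100.0, ("a1", "b2"): 90.0, ("b1", "a1"): 100.0},
            genome_of={"a1": "A", "b1": "B", "b2": "B"},
        )
        bets = best_hits(hits)
        assert bets.edges == [("a1", "b1", "symmetric")]

    def test_non_reciprocal_hit_is_asymmetric(self):
        hits = HitTable(
            scores={("a1", "b1"): 100.0, ("b1", "a2"): 120.0, ("b1", "a1"): 100.0},
            genome_of={"a1": "A", "a2": "A", "b1": "B"},
        )
        bets = best_hits(hits)
        kinds = {(a, b): k for a, b, k in bets.edges}
        assert kinds[("a1", "b1")] == "asymmetric"

    def test_matches_per_gene_argmax_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            hits = random_hit_table(rng)
            bets = best_hits(hits)
            edges = {(a, b): k for a, b, k in bets.edges}
            # oracle: exhaustive per-(gene, genome) argmax
            oracle_bets = {}
            for gene in hits.genome_of:
                for genome in {g for g in hits.genome_of.values()}:
                    if genome == hits.genome_of[gene]:
                        continue
                    cands = [
                        g for g in hits.genome_of
                        if hits.genome_of[g] == genome
                        and np.isfinite(hits.score(gene, g))
                    ]
                    if cands:
                        best = max(cands, key=lambda g: (hits.score(gene, g), g))
                        # ties break to lexicographically smallest id
                        top = hits.score(gene, best)
                        best = min(g for g in cands if hits.score(gene, g) == top)
                        oracle_bets[(gene, genome)] = best
            oracle_edges = {}
            for (gene, _), target in oracle_bets.items():
                key = (min(gene, target), max(gene, target))
                reciprocal = (
                    oracle_bets.get((target, hits.genome_of[gene])) == gene
                )
                kind = "symmetric" if reciprocal else "asymmetric"
                if oracle_edges.get(key) != "symmetric":
                    oracle_edges[key] = kind
            assert edges == oracle_edges


class TestCollapseParalogs:
    def _table(self, within, cross):
        # two genes in genome A, one foreign gene f1
        return HitTable(
            scores={("a1", "a2"): within, ("a1", "f1"): cross, ("a2", "f1"): 50.0},
            genome_of={"a1": "A", "a2": "A", "f1": "B"},
        )

    def test_dominant_pair_collapsed(self):
        groups = collapse_paralogs(self._table(200.0, 150.0), ["a1", "a2"])
        assert groups == [{"a1", "a2"}]

    def test_dominance_violated_not_collapsed(self):
        groups = collapse_paralogs(self._table(120.0, 150.0), ["a1", "a2"])
        assert groups == [{"a1"}, {"a2"}]

    def test_mixed_genome_input_rejected(self):
        with pytest.raises(ValueError):
            collapse_paralogs(self._table(1.0, 1.0), ["a1", "f1"])

    def test_matches_brute_force_dominance_partition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            hits = random_hit_table(rng, n_genomes=3, genes_per_genome=3)
            genes = [g for g, gn in hits.genome_of.items() if gn == "g0"]
            groups = collapse_paralogs(hits, genes)
            g = nx.Graph()
            g.add_nodes_from(genes)
            for a, b in itertools.combinations(genes, 2):
                s = hits.score(a, b)
                if s > hits.cross_genome_max(a) and s > hits.cross_genome_max(b):
                    g.add_edge(a, b)
            oracle = sorted(map(set, nx.connected_components(g)), key=min)
            assert groups == oracle


class TestExpandFromSeed:
    def test_seed_without_hits_is_fixed_point(self):
        hits = HitTable(scores={}, genome_of={"a1": "A", "b1": "B"})
        assert expand_from_seed("a1", hits) == {"a1"}

    def test_two_step_chain_closure(self):
        hits = HitTable(
            scores={("a1", "b1"): 100.0, ("b1", "c1"): 100.0},
            genome_of={"a1": "A", "b1": "B", "c1": "C"},
        )
        assert expand_from_seed("a1", hits) == {"a1", "b1", "c1"}

    def test_missing_seed_rejected(self):
        with pytest.raises(KeyError):
            expand_from_seed("zz", HitTable(scores={}, genome_of={"a": "A"}))

    def test_matches_reachability_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            hits = random_hit_table(rng, n_genomes=3, genes_per_genome=3, p_hit=0.5)
            seed = sorted(hits.genome_of)[0]
            closure = expand_from_seed(seed, hits)
            # oracle: reachability over BeT edges plus paralog-group edges
            g = nx.DiGraph()
            g.add_nodes_from(hits.genome_of)
            genomes = sorted(set(hits.genome_of.values()))
            for gene in hits.genome_of:
                for genome in genomes:
                    if genome == hits.genome_of[gene]:
                        continue
                    cands = [
                        x for x in hits.genome_of
                        if hits.genome_of[x] == genome
                        and np.isfinite(hits.score(gene, x))
                    ]
                    if cands:
                        top = max(hits.score(gene, x) for x in cands)
                        best = min(
                            x for x in cands if hits.score(gene, x) == top
                        )
                        g.add_edge(gene, best)
            for genome in genomes:
                genes = [x for x, gn in hits.genome_of.items() if gn == genome]
                for group in collapse_paralogs(hits, genes):
                    for a, b in itertools.combinations(sorted(group), 2):
                        g.add_edge(a, b)
                        g.add_edge(b, a)
            oracle = {seed} | nx.descendants(g, seed)
            assert closure == oracle


class TestFormCogs:
    def _graph(self, edges, genome_of):
        return BeTGraph(nodes=set(genome_of), genome_of=genome_of, edges=edges)

    def test_single_triangle(self):
        bets = self._graph(
            [("a", "b", "symmetric"), ("a", "c", "symmetric"), ("b", "c", "symmetric")],
            {"a": "A", "b": "B", "c": "C"},
        )
        (cog,) = form_cogs(bets)
        assert cog.members == ["a", "b", "c"]

    def test_triangles_sharing_an_edge_merge(self):
        bets = self._graph(
            [
                ("a", "b", "symmetric"),
                ("a", "c", "symmetric"),
                ("b", "c", "symmetric"),
                ("a", "d", "symmetric"),
                ("b", "d", "asymmetric"),
            ],
            {"a": "A", "b": "B", "c": "C", "d": "D"},
        )
        (cog,) = form_cogs(bets)
        assert cog.members == ["a", "b", "c", "d"]

    def test_two_genome_triangle_excluded(self):
        # a triangle spanning only two genomes must not form a cluster
        bets = self._graph(
            [("a1", "b1", "symmetric"), ("a1", "b2", "symmetric"), ("b1", "b2", "symmetric")],
            {"a1": "A", "b1": "B", "b2": "B"},
        )
        assert form_cogs(bets) == []

    def test_invariant_to_gene_ordering(self):
        rng = np.random.default_rng(3)
        hits = random_hit_table(rng)
        bets = best_hits(hits)
        shuffled = BeTGraph(
            nodes=bets.nodes,
            genome_of=bets.genome_of,
            edges=list(reversed(bets.edges)),
        )
        a = [(c.cluster_id, c.members) for c in form_cogs(bets)]
        b = [(c.cluster_id, c.members) for c in form_cogs(shuffled)]
        assert a == b

    def test_matches_triangle_merge_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            hits = random_hit_table(rng, n_genomes=4, genes_per_genome=3, p_hit=0.4)
            bets = best_hits(hits)
            clusters = {frozenset(c.members) for c in form_cogs(bets)}
            assert clusters == triangle_merge_oracle(bets)


def triangle_merge_oracle(bets: BeTGraph) -> set[frozenset]:
    """Independent oracle: enumerate all 3-genome triangles, union on shared edges."""
    adj = bets.undirected()
    triangles = []
    nodes = sorted(adj.nodes)
    for a, b, c in itertools.combinations(nodes, 3):
        if (
            adj.has_edge(a, b) and adj.has_edge(a, c) and adj.has_edge(b, c)
            and len({bets.genome_of[a], bets.genome_of[b], bets.genome_of[c]}) == 3
        ):
            triangles.append((a, b, c))
    g = nx.Graph()
    for a, b, c in triangles:
        g.add_edges_from([(a, b), (a, c), (b, c)])
    return {frozenset(comp) for comp in nx.connected_components(g)}


class TestRecoveryAndExport:
    def test_recovers_simulated_families_exactly(self, small_genomes):
        genomes, truths = small_genomes
        threshold = cogfinder.background_min_score(genomes, seed=0)
        hits = all_against_all(genomes, min_score=threshold)
        clusters = form_cogs(best_hits(hits))
        recovered = {frozenset(c.members) for c in clusters}
        truth = {frozenset(m for _, m in t.members) for t in truths}
        assert recovered == truth  # precision = recall = 1

    def test_seed_choice_does_not_change_closure(self, small_genomes):
        genomes, truths = small_genomes
        hits = all_against_all(
            genomes, min_score=cogfinder.background_min_score(genomes, seed=0)
        )
        members = [m for _, m in truths[0].members]
        closures = {frozenset(expand_from_seed(m, hits)) for m in members}
        assert closures == {frozenset(members)}

    def test_network_export_round_trip(self, tmp_path):
        bets = BeTGraph(
            nodes={"a", "b", "c"},
            genome_of={"a": "A", "b": "B", "c": "C"},
            edges=[
                ("a", "b", "symmetric"),
                ("a", "c", "symmetric"),
                ("b", "c", "asymmetric"),
            ],
        )
        (cog,) = form_cogs(bets)
        cogfinder.export_network(cog, tmp_path / "net")
        back = cogfinder.read_network(tmp_path / "net.tsv")
        assert back == sorted(cog.edges)
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert {
            (min(a, b), max(a, b), d["kind"]) for a, b, d in g.edges(data=True)
        } == set(cog.edges)
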