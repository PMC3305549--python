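"""Synthetic genomes and codon alignments with known evolutionary truth.

Two generators feed the test surface of the whole pipeline:

* :func:`simulate_codon_alignment` evolves indel-free codon alignments on a
  labeled tree under the GY94 model, with per-site ω classes that may vary
  by branch class — the ground truth for branch and branch-site inference.
  Branch endpoints are sampled exactly from the rows of ``P(t) = exp(Qt)``,
  which is distributionally identical to event-by-event simulation.

* :func:`simulate_genomes` evolves gene families on a species tree with
  Poisson duplications and exponential losses, producing per-genome
  protein+CDS records plus a replayable event log, alongside unrelated
  decoy families seeded from independent root sequences (background-level
  cross-family similarity by construction).

All randomness flows from a single integer seed; per-family child seeds are
derived by the fixed arithmetic ``(seed * 1_000_003 + index) % 2**31``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codons import CODONS, N_CODONS
from .codonalign import CodonAlignment
from .genomes import GeneRecord, Genome, GenomeSet
from .codonmodel import _rate_matrix, _syn_flows, transition_probs
from .trees import LabeledTree, balanced_tree

__all__ = [
    "SimRegime",
    "FamilyTruth",
    "simulate_codon_alignment",
    "simulate_genomes",
    "write_fixture",
    "uniform_codon_freqs",
]


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


@dataclass
class SimRegime:
    """One simulation condition for codon-alignment evolution.

    ``site_classes`` is a list of ``(proportion, omega_by_branch_class)``
    pairs; each site is assigned a class with the given probability, and a
    branch labeled ``k`` evolves that site with ``omega_by_branch_class[k]``.
    A single class with a single-entry ω map is the plain one-ratio model.
    """

    tree: LabeledTree
    kappa: float
    codon_freqs: np.ndarray
    site_classes: list[tuple[float, dict[int, float]]]
    n_codons: int
    seed: int
    #: "per-matrix": every (class, branch) generator is normalized to one
    #: expected substitution per codon (branch-model convention);
    #: "shared": all site classes share one rate scale anchored on
    #: class-0 branches, so high-ω classes evolve proportionally faster
    #: (the branch-site convention).
    scaling: str = "per-matrix"

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        if not self.tree.leaf_names:
            raise ValueError("empty tree")
        props = [p for p, _ in self.site_classes]
        if abs(sum(props) - 1.0) > 1e-8 or any(p < 0 for p in props):
            raise ValueError("site-class proportions must be nonnegative and sum to 1")
        for _, omap in self.site_classes:
            if any(w < 0 for w in omap.values()):
                raise ValueError("omega values must be >= 0")
        for lab in self.tree.branch_classes():
            for _, omap in self.site_classes:
                if lab not in omap:
                    raise ValueError(f"branch class {lab} missing from a site-class omega map")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon_freqs must sum to 1")
        if self.scaling not in ("per-matrix", "shared"):
            raise ValueError("scaling must be 'per-matrix' or 'shared'")


def _sample_children(parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states per site from the parent-state rows of P."""
    out = np.empty_like(parent_states)
    for s in np.unique(parent_states):
        mask = parent_states == s
        out[mask] = rng.choice(N_CODONS, size=int(mask.sum()), p=p[s] / p[s].sum())
    return out


def simulate_codon_alignment(regime: SimRegime) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve an indel-free codon alignment; returns (alignment, site classes).

    Sites are iid: class drawn from the regime proportions, root codon from
    the equilibrium frequencies, then codon states transit branch by branch
    under the class/branch-specific GY94 matrix.  Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(regime.seed)
    n = regime.n_codons
    props = np.array([p for p, _ in regime.site_classes])
    site_class = rng.choice(len(props), size=n, p=props)
    root_states = rng.choice(N_CODONS, size=n, p=regime.codon_freqs / regime.codon_freqs.sum())

    # transition matrices per (site class, branch) — branches keyed by node id
    nodes = regime.tree.postorder()
    preorder = nodes[::-1]  # root first
    if regime.scaling == "shared":
        s1, n1 = _syn_flows(regime.kappa, regime.codon_freqs)
        scale = sum(
            p * (s1 + omap[0] * n1) for p, omap in regime.site_classes
        )
    pmat: dict[tuple[int, int], np.ndarray] = {}
    qcache: dict[float, np.ndarray] = {}
    for ci, (_, omap) in enumerate(regime.site_classes):
        for node in preorder[1:]:
            omega = omap[node.label]
            if omega not in qcache:
                qcache[omega] = _rate_matrix(regime.kappa, omega, regime.codon_freqs)
            t = node.length
            if regime.scaling == "shared":
                t = t * (s1 + omega * n1) / scale
            pmat[(ci, id(node))] = transition_probs(qcache[omega], t, regime.codon_freqs)

    states: dict[int, np.ndarray] = {id(preorder[0]): root_states}
    parent_of: dict[int, int] = {}

    def link(node) -> None:
        for c in node.children:
            parent_of[id(c)] = id(node)
            link(c)

    link(regime.tree.root)
    for node in preorder[1:]:
        parent_states = states[parent_of[id(node)]]
        child = np.empty(n, dtype=parent_states.dtype)
        for ci in range(len(regime.site_classes)):
            mask = site_class == ci
            if mask.any():
                child[mask] = _sample_children(
                    parent_states[mask], pmat[(ci, id(node))], rng
                )
        states[id(node)] = child

    names, rows = [], []
    for node in nodes:
        if node.is_leaf:
            names.append(node.name)
            rows.append("".join(CODONS[s] for s in states[id(node)]))
    return CodonAlignment(names, rows), site_class


# ---------------------------------------------------------------------------
# genome-scale simulation


@dataclass
class FamilyTruth:
    """Ground truth for one simulated gene family.

    ``event_log`` records duplications and losses as
    ``{"event", "branch", "lineage", ["new_lineage"]}`` dicts; replaying it
    on the species tree reproduces the member set exactly.
    """

    family_id: str
    members: list[tuple[str, str]]
    event_log: list[dict] = field(default_factory=list)

    def replay(self, species_tree: LabeledTree) -> list[tuple[str, str]]:
        """Recompute the member set from the event log alone."""
        by_branch: dict[str, list[dict]] = {}
        for ev in self.event_log:
            by_branch.setdefault(ev["branch"], []).append(ev)
        members: list[tuple[str, str]] = []

        def walk(node, lineages: list[str], branch_name: str) -> None:
            for ev in by_branch.get(branch_name, []):
                if ev["event"] == "loss":
                    lineages = [x for x in lineages if x != ev["lineage"]]
                elif ev["event"] == "duplication":
                    lineages = lineages + [ev["new_lineage"]]
            if node.is_leaf:
                for lin in lineages:
                    members.append((node.name, _gene_id(node.name, self.family_id, lin)))
            else:
                for k, child in enumerate(node.children):
                    walk(child, list(lineages), _branch_name(branch_name, k, child))

        walk(species_tree.root, ["g"], "root")
        return sorted(members)


def _branch_name(parent: str, k: int, child) -> str:
    return child.name if child.is_leaf else f"{parent}.{k}"


def _gene_id(genome_id: str, family_id: str, lineage: str) -> str:
    return f"{genome_id}__{family_id}__{lineage}"


def _evolve_family(
    family_id: str,
    species_tree: LabeledTree,
    *,
    kappa: float,
    omega: float | dict[int, float] | list[tuple[float, dict[int, float]]],
    codon_freqs: np.ndarray,
    n_codons: int,
    dup_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[str, str]]], FamilyTruth]:
    """Evolve one family; returns per-genome [(gene_id, cds)] and its truth.

    ``omega`` may be a single dN/dS value, a map from species-tree branch
    class labels to ω (lineage-specific regimes), or a site-class mixture
    ``[(proportion, {label: ω}), ...]`` for episodic branch-site selection.
    """
    if isinstance(omega, list):
        # site-class mixture: [(proportion, {branch label: omega}), ...]
        # with one shared rate scale anchored on label-0 branches (the
        # branch-site convention)
        site_classes = omega
        s1, n1 = _syn_flows(kappa, codon_freqs)
        scale = sum(p * (s1 + omap[0] * n1) for p, omap in site_classes)
    else:
        omega_map = (
            omega if isinstance(omega, dict)
            else {lab: omega for lab in species_tree.branch_classes() | {0}}
        )
        site_classes = [(1.0, omega_map)]
        s1 = n1 = scale = None
    qcache: dict[float, np.ndarray] = {}

    def branch_p(label: int, t: float) -> list[np.ndarray]:
        """Transition matrix per site class for one branch."""
        out = []
        for _, omap in site_classes:
            w = omap[label]
            if w not in qcache:
                qcache[w] = _rate_matrix(kappa, w, codon_freqs)
            t_eff = t if scale is None else t * (s1 + w * n1) / scale
            out.append(transition_probs(qcache[w], t_eff, codon_freqs))
        return out

    root_seq = rng.choice(N_CODONS, size=n_codons, p=codon_freqs / codon_freqs.sum())
    props = np.array([p for p, _ in site_classes])
    site_class = rng.choice(len(props), size=n_codons, p=props / props.sum())
    genes: dict[str, list[tuple[str, str]]] = {}
    log: list[dict] = []

    def evolve(seq: np.ndarray, pmats: list[np.ndarray]) -> np.ndarray:
        out = np.empty_like(seq)
        for ci, p in enumerate(pmats):
            mask = site_class == ci
            if mask.any():
                out[mask] = _sample_children(seq[mask], p, rng)
        return out

    def walk(node, lineages: list[tuple[str, np.ndarray]], branch_name: str) -> None:
        if branch_name != "root":
            t = node.length
            survived = []
            for lin, seq in lineages:
                if rng.random() > np.exp(-loss_rate * t):
                    log.append({"event": "loss", "branch": branch_name, "lineage": lin})
                    continue
                survived.append((lin, seq))
            expanded = []
            for lin, seq in survived:
                copies = [(lin, seq)]
                for d in range(rng.poisson(dup_rate * t)):
                    new_lin = f"{lin}d{sum(1 for e in log if e['event'] == 'duplication' and e['lineage'] == lin) + 1}"
                    log.append(
                        {"event": "duplication", "branch": branch_name,
                         "lineage": lin, "new_lineage": new_lin}
                    )
                    copies.append((new_lin, seq))
                expanded.extend(copies)
            pmats = branch_p(node.label, t) if t > 0 else None
            lineages = [
                (lin, seq if pmats is None else evolve(seq, pmats))
                for lin, seq in expanded
            ]
        if node.is_leaf:
            genes[node.name] = [
                (_gene_id(node.name, family_id, lin), "".join(CODONS[s] for s in seq))
                for lin, seq in lineages
            ]
        else:
            for k, child in enumerate(node.children):
                walk(child, [(lin, seq) for lin, seq in lineages], _branch_name(branch_name, k, child))

    walk(species_tree.root, [("g", root_seq)], "root")
    members = sorted(
        (genome, gid) for genome, lst in genes.items() for gid, _ in lst
    )
    return genes, FamilyTruth(family_id=family_id, members=members, event_log=log)


def simulate_genomes(
    n_genomes: int,
    n_decoy_families: int,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    *,
    n_target_families: int = 1,
    n_codons: int = 200,
    kappa: float = 2.0,
    omega: float | dict[int, float] = 0.2,
    target_omega: float | dict[int, float] | list[tuple[float, dict[int, float]]] | None = None,
    codon_freqs: np.ndarray | None = None,
    species_tree: LabeledTree | None = None,
    species_branch_length: float = 1.0,
) -> tuple[GenomeSet, list[FamilyTruth]]:
    """Simulate genomes containing known gene families plus decoys.

    Every family (targets first, then decoys) evolves independently on the
    species tree from its own random root sequence, with per-branch Poisson
    duplications (rate ``dup_rate`` per unit branch length) and exponential
    losses (rate ``loss_rate``).  With both rates zero every family has
    exactly one member per genome.  ``target_omega``, when given, overrides
    ``omega`` for the target families only (e.g. a site-class mixture
    planting episodic positive selection on a labeled clade, while decoys
    evolve under uniform purifying selection).
    """
    if n_genomes < 2:
        raise ValueError("need at least two genomes")
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if codon_freqs is None:
        codon_freqs = uniform_codon_freqs()
    if species_tree is None:
        species_tree = balanced_tree(
            [f"g{i}" for i in range(n_genomes)], branch_length=species_branch_length
        )
    elif species_tree.n_leaves != n_genomes:
        raise ValueError("species_tree leaf count != n_genomes")

    genome_set = GenomeSet()
    for name in species_tree.leaf_names:
        genome_set.add(Genome(name))

    truths: list[FamilyTruth] = []
    n_families = n_target_families + n_decoy_families
    for fam_idx in range(n_families):
        fam_seed = (seed * 1_000_003 + fam_idx) % 2**31
        rng = np.random.default_rng(fam_seed)
        is_target = fam_idx < n_target_families
        role = "fam" if is_target else "decoy"
        fam_id = f"{role}{fam_idx:03d}"
        genes, truth = _evolve_family(
            fam_id,
            species_tree,
            kappa=kappa,
            omega=(target_omega if is_target and target_omega is not None else omega),
            codon_freqs=codon_freqs,
            n_codons=n_codons,
            dup_rate=dup_rate,
            loss_rate=loss_rate,
            rng=rng,
        )
        for genome_id, lst in genes.items():
            for gid, cds in lst:
                genome_set.genomes[genome_id].add(
                    GeneRecord.from_cds(gid, cds, family_id=fam_id)
                )
        truths.append(truth)
    return genome_set, truths


def write_fixture(genomes: GenomeSet, out_dir: str | Path, *, seed: int | None = None) -> dict:
    """Persist a GenomeSet as FASTA + truth TSV; returns the manifest."""
    manifest = genomes.write(out_dir)
    if seed is not None:
        import json

        manifest["seed"] = seed
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest
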