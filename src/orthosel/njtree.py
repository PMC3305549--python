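"""Neighbor-joining protein phylogenies on JTT maximum-likelihood distances.

Pairwise distances are ML estimates under the JTT amino-acid replacement
model (rate matrix normalized to one expected substitution per site), with
pairwise deletion of gapped/ambiguous sites, a one-dimensional bounded
likelihood optimization per pair, and a saturation cap at 10
substitutions/site.  Trees are built with the Saitou–Nei neighbor-joining
algorithm (deterministic lexicographic tie-breaking, negative branch
lengths clamped to zero) and annotated with nonparametric bootstrap
support from column resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .codonalign import pairwise_shared_sites
from .trees import LabeledTree, Node

__all__ = [
    "DistanceMatrix",
    "jtt_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "write_distance_tsv",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
DISTANCE_CAP = 10.0


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Bundled JTT exchangeabilities (symmetric, zero diagonal) and frequencies."""
    text = (resources.files("orthosel.data") / "jtt.dat").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    s = np.zeros((20, 20))
    for i, ln in enumerate(lines[:19], start=1):
        vals = [float(v) for v in ln.split()]
        s[i, : len(vals)] = vals
    s = s + s.T
    pi = np.array([float(v) for v in lines[19].split()])
    return s, pi / pi.sum()


_JTT_CACHE: tuple | None = None


def _jtt_eigen():
    """Eigendecomposition of the normalized JTT generator (cached)."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        s, pi = _load_jtt()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        q /= -(pi * np.diag(q)).sum()
        sq = np.sqrt(pi)
        sym = (q * sq[:, None]) / sq[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2)
        right = u / sq[:, None]
        left = u.T * sq[None, :]
        _JTT_CACHE = (pi, right, lam, left)
    return _JTT_CACHE


def jtt_distance(row_a: str, row_b: str) -> float:
    """ML JTT distance (substitutions/site) between two aligned protein rows.

    Sites gapped or ambiguous in either row are excluded (pairwise
    deletion); at least one shared site is required.  The estimate is the
    argmax over t ∈ [0, 10] of Σ log[π_a P_ab(t)]; estimates at the cap
    trigger a saturation warning.
    """
    shared = [
        i for i in pairwise_shared_sites(row_a, row_b, ambiguous={"X"})
        if row_a[i].upper() in _AA_INDEX and row_b[i].upper() in _AA_INDEX
    ]
    if not shared:
        raise ValueError("no shared unambiguous sites after pairwise deletion")
    pi, right, lam, left = _jtt_eigen()
    ia = np.array([_AA_INDEX[row_a[i].upper()] for i in shared])
    ib = np.array([_AA_INDEX[row_b[i].upper()] for i in shared])
    pairs = ia * 20 + ib
    uniq, counts = np.unique(pairs, return_counts=True)
    ua, ub = uniq // 20, uniq % 20
    w = counts.astype(float)
    if np.array_equal(ua, ub):
        return 0.0

    def neg_ll(t: float) -> float:
        p = (right * np.exp(lam * t)) @ left
        lik = pi[ua] * np.clip(p[ua, ub], 1e-300, None)
        return -float(w @ np.log(lik))

    res = minimize_scalar(neg_ll, bounds=(0.0, DISTANCE_CAP), method="bounded",
                          options={"xatol": 1e-8})
    t = float(res.x)
    if t > DISTANCE_CAP - 1e-3:
        warnings.warn("JTT distance at saturation cap (10 substitutions/site)")
        t = DISTANCE_CAP
    return t


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair shared-site counts."""

    labels: list[str]
    matrix: np.ndarray
    shared_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("distances must be finite")


def distance_matrix(names: list[str], rows: list[str]) -> DistanceMatrix:
    """Pairwise JTT ML distance matrix of an aligned protein MSA."""
    n = len(names)
    dm = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared[i, i] = len(rows[i])
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jtt_distance(rows[i], rows[j])
            ns = len(pairwise_shared_sites(rows[i], rows[j], ambiguous={"X"}))
            shared[i, j] = shared[j, i] = ns
    return DistanceMatrix(labels=list(names), matrix=dm, shared_sites=shared)


def neighbor_joining(dm: DistanceMatrix) -> LabeledTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Deterministic under ties (the candidate pair with lexicographically
    smallest cluster keys wins); negative branch-length solutions are
    clamped to zero.  Returns an unrooted tree (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[Node] = [Node(name=lbl) for lbl in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest leaf inside each cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_new[m - 2, : m - 2] = d_new[: m - 2, m - 2] = du[keep]
        d = d_new
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [u]
        keys = [keys[k] for k in keep] + [new_key]

    # final three-way join: closed-form branch lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    root = Node(children=[a, b, c])
    return LabeledTree(root)


def bootstrap_support(
    names: list[str],
    rows: list[str],
    n_reps: int = 1000,
    seed: int = 0,
) -> LabeledTree:
    """NJ tree with nonparametric bootstrap support on internal branches.

    Columns are resampled with replacement ``n_reps`` times; support of a
    split in the full-data tree is the fraction of replicate trees
    containing it.  Seeded and deterministic.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distance_matrix(names, rows))
    length = len(rows[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_rows = ["".join(r[c] for c in cols) for r in rows]
        rep_tree = neighbor_joining(distance_matrix(names, rep_rows))
        for split in rep_tree.splits():
            counts[split] = counts.get(split, 0) + 1

    all_names = frozenset(names)

    def annotate(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 1 < len(below) < len(all_names) - 1:
            split = min(below, all_names - below, key=lambda s: (len(s), sorted(s)))
            node.support = counts.get(split, 0) / n_reps
        return below

    annotate(tree.root)
    return tree


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """PHYLIP-style (labeled square) distance matrix as TSV."""
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(dm.labels) + "\n")
        for lbl, row in zip(dm.labels, dm.matrix):
            fh.write(lbl + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
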