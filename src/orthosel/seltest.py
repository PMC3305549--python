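"""Selection inference: branch-specific ω models, branch-site Model A, LRTs
and per-site posterior probabilities of positive selection.

The branch-specific model assigns one ω per branch class and is compared to
the one-ratio model by a likelihood ratio test with df equal to the
difference in the number of ω classes.  The branch-site model (Model A)
mixes four site classes — conserved (ω0 < 1 everywhere), neutral (ω1 = 1
everywhere), and two classes where background branches keep ω0 or 1 while
the designated foreground branches evolve with ω2 ≥ 1.  The null
hypothesis fixes ω2 = 1; the alternative frees ω2 ≥ 1; the LRT uses the
χ²(1) reference (conservative relative to the 50:50 point-mass mixture).
Per-site posteriors of the positively selected classes are computed either
naively at the MLEs (NEB) or by Bayes empirical Bayes (BEB), averaging
over a discrete prior grid on the mixture proportions and ω0, ω2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from .codonalign import CodonAlignment
from .codonmodel import (
    ModelFit,
    PruningEngine,
    _syn_flows,
    f3x4_frequencies,
    fit as gy94_fit,
)
from .trees import LabeledTree

__all__ = [
    "BranchModelSpec",
    "LRTResult",
    "ModelAFit",
    "BranchSiteResult",
    "SitePosterior",
    "fit_branch_model",
    "lrt",
    "fit_model_a",
    "branch_site_test",
    "site_posteriors",
    "make_table",
]


@dataclass
class BranchModelSpec:
    """Named branch model: tree branch label → ω class (0..K−1).

    ``class_map`` keys are the labels carried by the tree's branches; with
    all labels mapped to class 0 this is the one-ratio model.
    """

    name: str
    class_map: dict[int, int]

    @property
    def n_classes(self) -> int:
        return max(self.class_map.values()) + 1

    def validate(self, tree: LabeledTree) -> None:
        labels = tree.branch_classes()
        missing = labels - set(self.class_map)
        if missing:
            raise ValueError(f"branch labels {sorted(missing)} not covered by spec {self.name!r}")
        classes = set(self.class_map.values())
        if classes != set(range(self.n_classes)):
            raise ValueError("omega classes must be contiguous 0..K-1 and include 0")


def fit_branch_model(
    aln: CodonAlignment, tree: LabeledTree, spec: BranchModelSpec, **fit_kwargs
) -> ModelFit:
    """Fit the branch-specific GY94 model defined by ``spec``.

    The tree's branch labels are re-mapped to the spec's ω classes and the
    fit is delegated to the codon-model optimizer; K = 1 reduces exactly to
    the one-ratio model.
    """
    spec.validate(tree)
    relabeled = tree.copy()
    for node in relabeled.postorder()[:-1]:
        node.label = spec.class_map[node.label]
    relabeled.root.label = 0
    mf = gy94_fit(
        aln, relabeled, n_omega_classes=spec.n_classes,
        model_name=spec.name, **fit_kwargs,
    )
    return mf


@dataclass
class LRTResult:
    """Paired-model likelihood ratio test (2ΔlnL against χ²(df))."""

    lnL_null: float
    lnL_alt: float
    df: int
    statistic: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lnL_null) and np.isfinite(self.lnL_alt)):
            raise ValueError("log-likelihoods must be finite")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        stat = 2.0 * (self.lnL_alt - self.lnL_null)
        if stat < 0:
            if stat < -1e-4:
                warnings.warn(
                    f"negative LRT statistic {stat:.3g} clamped to 0 "
                    "(alternative fit worse than null — optimizer slack)"
                )
            stat = 0.0
        self.statistic = stat
        self.p_value = float(chi2.sf(stat, self.df)) if stat > 0 else 1.0


def lrt(lnL_null: float, lnL_alt: float, df: int) -> LRTResult:
    """LRT from two log-likelihoods: statistic 2(lnL_alt − lnL_null)."""
    return LRTResult(lnL_null=lnL_null, lnL_alt=lnL_alt, df=df)


# ---------------------------------------------------------------------------
# branch-site Model A


@dataclass
class ModelAFit:
    """Fitted branch-site Model A (null: ω2 ≡ 1; alternative: ω2 ≥ 1)."""

    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    lnL: float
    null: bool
    foreground: set[int]
    branch_lengths: np.ndarray
    codon_freqs: np.ndarray
    n_free_params: int
    converged: bool = True
    omega1: float = 1.0

    @property
    def p2a(self) -> float:
        return (1 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    @property
    def p2_plus_p3(self) -> float:
        """Total proportion of foreground-selected sites (2a + 2b)."""
        return self.p2a + self.p2b


class _ModelAEngine:
    """Shared machinery for Model A likelihood and posteriors."""

    def __init__(
        self,
        aln: CodonAlignment,
        tree: LabeledTree,
        foreground: set[int],
        codon_freqs: np.ndarray,
    ):
        labels = tree.branch_classes()
        fg = set(foreground)
        if not fg & labels:
            raise ValueError("foreground labels not found on the tree")
        if labels <= fg:
            raise ValueError("foreground cannot cover every branch (no background left)")
        self.engine = PruningEngine(aln, tree)
        self.engine.set_frequencies(codon_freqs)
        branch_labels = self.engine.tree_index.labels
        self.is_fg = np.array([lab in fg for lab in branch_labels])
        self.foreground = fg

    def scale_factor(self, kappa: float, omega0: float, weights: np.ndarray) -> float:
        """Common rate scale across the four site classes.

        One scale factor is shared by all site classes (the codeml
        convention), chosen so the expected substitution rate on background
        branches, averaged over site classes at the current mixture
        weights, is one per unit branch length.  Positively selected sites
        therefore evolve faster on the foreground, which is most of the
        detectable signal.
        """
        s1, n1 = _syn_flows(kappa, self.engine._pi)
        r0 = s1 + omega0 * n1
        r1 = s1 + n1
        return float((weights[0] + weights[2]) * r0 + (weights[1] + weights[3]) * r1)

    def class_site_lls(
        self,
        kappa: float,
        omega0: float,
        omega2: float,
        lengths: np.ndarray | None,
        weights: np.ndarray,
        scale: float | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood under each of the four site classes.

        ``lengths`` are nominal branch lengths; each class/branch gets an
        effective length ``t · R(ω)/scale`` where R is the unnormalized
        rate of its GY94 matrix.
        """
        nb = len(self.is_fg)
        if lengths is None:
            lengths = self.engine.tree_index.lengths
        if scale is None:
            scale = self.scale_factor(kappa, omega0, weights)
        s1, n1 = _syn_flows(kappa, self.engine._pi)
        w0 = np.full(nb, omega0)
        w1 = np.ones(nb)
        w2a = np.where(self.is_fg, omega2, omega0)
        w2b = np.where(self.is_fg, omega2, 1.0)
        out = []
        for w in (w0, w1, w2a, w2b):
            # per-matrix-normalized generators with rescaled lengths give
            # exactly the shared-scale unnormalized process
            t_eff = lengths * (s1 + w * n1) / scale
            out.append(self.engine.site_log_likelihoods(kappa, w, t_eff))
        return np.stack(out)

    def mixture_lnL(self, weights: np.ndarray, class_lls: np.ndarray) -> float:
        logw = np.log(np.maximum(weights, 1e-300))
        site = logsumexp(class_lls + logw[:, None], axis=0)
        return float(self.engine.pattern_weights @ site)


def fit_model_a(
    aln: CodonAlignment,
    tree: LabeledTree,
    foreground: set[int] | int = 1,
    null: bool = False,
    *,
    m0: ModelFit | None = None,
    fix_branch_lengths: bool = True,
    fix_kappa: bool = False,
    codon_freqs: np.ndarray | None = None,
    n_starts: int = 2,
    seed: int = 0,
    omega2_max: float = 999.0,
    init_params: dict | None = None,
) -> ModelAFit:
    """Fit branch-site Model A by maximum likelihood.

    ``foreground`` selects tree branch labels tested for positive
    selection (default: label 1, the PAML ``#1`` convention).  By default
    branch lengths (and optionally κ) are fixed at one-ratio (M0)
    estimates — computed internally when ``m0`` is not supplied — which is
    the fast mode; set ``fix_branch_lengths=False`` to re-optimize them
    jointly.
    """
    if isinstance(foreground, int):
        foreground = {foreground}
    if codon_freqs is None:
        codon_freqs = f3x4_frequencies(aln.rows)
    work = _ModelAEngine(aln, tree, foreground, codon_freqs)
    ti = work.engine.tree_index

    if m0 is None:
        m0 = gy94_fit(
            aln, tree, n_omega_classes=1, codon_freqs=codon_freqs,
            n_starts=1, seed=seed, model_name="one-ratio",
        )
    init_lengths = m0.branch_lengths
    kappa0 = m0.params.kappa
    n_branches = len(init_lengths)

    # parameters: theta1 = p0+p1, theta2 = p0/(p0+p1), omega0,
    # [omega2 (alt)], [kappa], [branch lengths]
    init_params = init_params or {}
    p0i = init_params.get("p0", 0.56)
    p1i = init_params.get("p1", 0.24)
    th1 = min(max(p0i + p1i, 1e-4), 1 - 1e-4)
    th2 = min(max(p0i / (p0i + p1i), 1e-4), 1 - 1e-4)
    bounds = [(1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4), (1e-4, 1.0)]
    x0_base = [th1, th2, init_params.get("omega0", 0.3)]
    if not null:
        bounds.append((1.0, omega2_max))
        x0_base.append(init_params.get("omega2", 2.0))
    if not fix_kappa:
        bounds.append((0.05, 50.0))
        x0_base.append(kappa0)
    if not fix_branch_lengths:
        bounds.extend([(1e-8, 50.0)] * n_branches)
        x0_base.extend(np.maximum(init_lengths, 1e-4).tolist())
    x0_base = np.asarray(x0_base)

    def unpack(x):
        th1, th2, w0 = x[0], x[1], x[2]
        k = 3
        if null:
            w2 = 1.0
        else:
            w2 = x[k]
            k += 1
        if fix_kappa:
            kap = kappa0
        else:
            kap = x[k]
            k += 1
        if fix_branch_lengths:
            lens = np.append(init_lengths, 0.0)
        else:
            lens = np.append(x[k:], 0.0)
        p0, p1 = th1 * th2, th1 * (1 - th2)
        return p0, p1, w0, w2, kap, lens

    def objective(x):
        p0, p1, w0, w2, kap, lens = unpack(x)
        rest = 1 - p0 - p1
        weights = np.array(
            [p0, p1, rest * p0 / (p0 + p1), rest * p1 / (p0 + p1)]
        )
        class_lls = work.class_site_lls(kap, w0, w2, lens, weights)
        ll = work.mixture_lnL(weights, class_lls)
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x0 = x0_base.copy()
        if start > 0:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            x0 = np.clip(x0 * np.exp(rng.normal(0, 0.3, x0.size)), lo, hi)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    p0, p1, w0, w2, kap, lens = unpack(best.x)
    n_free = (
        3 + (0 if null else 1) + (0 if fix_kappa else 1)
        + (0 if fix_branch_lengths else n_branches)
    )
    return ModelAFit(
        p0=float(p0), p1=float(p1), omega0=float(w0), omega2=float(w2),
        kappa=float(kap), lnL=float(-best.fun), null=null,
        foreground=set(foreground), branch_lengths=lens[:-1].copy(),
        codon_freqs=codon_freqs, n_free_params=n_free,
        converged=bool(best.success),
    )


@dataclass
class BranchSiteResult:
    """Null and alternative Model A fits with their LRT."""

    null_fit: ModelAFit
    alt_fit: ModelAFit
    test: LRTResult


def branch_site_test(
    aln: CodonAlignment,
    tree: LabeledTree,
    foreground: set[int] | int = 1,
    **kwargs,
) -> BranchSiteResult:
    """Run the branch-site positive-selection LRT for one foreground.

    Fits Model A under the null (ω2 = 1) and the alternative (ω2 ≥ 1) and
    compares them with a χ²(1) LRT.  An M0 fit is shared between the two
    fits when branch lengths are fixed.
    """
    if kwargs.get("fix_branch_lengths", True) and kwargs.get("m0") is None:
        codon_freqs = kwargs.get("codon_freqs")
        if codon_freqs is None:
            codon_freqs = f3x4_frequencies(aln.rows)
            kwargs["codon_freqs"] = codon_freqs
        kwargs["m0"] = gy94_fit(
            aln, tree, n_omega_classes=1, codon_freqs=codon_freqs,
            n_starts=1, seed=kwargs.get("seed", 0), model_name="one-ratio",
        )
    null_fit = fit_model_a(aln, tree, foreground, null=True, **kwargs)
    # seed the alternative from the null optimum (the models are nested)
    # at two ω2 starting points to dodge the ω2=1 boundary optimum
    candidates = []
    for w2_start in (2.0, 8.0):
        candidates.append(
            fit_model_a(
                aln, tree, foreground, null=False,
                init_params={
                    "p0": null_fit.p0, "p1": null_fit.p1,
                    "omega0": null_fit.omega0, "omega2": w2_start,
                },
                **kwargs,
            )
        )
    alt_fit = max(candidates, key=lambda f: f.lnL)
    if alt_fit.lnL < null_fit.lnL:
        # ω2 = 1 lies in the alternative space: the null optimum is a
        # valid alternative solution, so never report anything worse
        alt_fit = ModelAFit(
            p0=null_fit.p0, p1=null_fit.p1, omega0=null_fit.omega0,
            omega2=1.0, kappa=null_fit.kappa, lnL=null_fit.lnL, null=False,
            foreground=null_fit.foreground,
            branch_lengths=null_fit.branch_lengths,
            codon_freqs=null_fit.codon_freqs,
            n_free_params=null_fit.n_free_params + 1,
            converged=null_fit.converged,
        )
    return BranchSiteResult(
        null_fit=null_fit,
        alt_fit=alt_fit,
        test=lrt(null_fit.lnL, alt_fit.lnL, df=1),
    )


# ---------------------------------------------------------------------------
# site posteriors


@dataclass
class SitePosterior:
    """Per-site posterior probability of the positively selected classes."""

    method: str
    p_selected: np.ndarray          # per original site, P(class 2a ∪ 2b | data)
    class_posteriors: np.ndarray | None = None  # (n_sites, 4), NEB only


def _expand(engine: PruningEngine, per_pattern: np.ndarray) -> np.ndarray:
    return per_pattern[..., engine.pattern_of_site]


def site_posteriors(
    fit: ModelAFit,
    aln: CodonAlignment,
    tree: LabeledTree,
    method: str = "BEB",
    *,
    grid_levels: int = 10,
    omega2_prior_max: float = 11.0,
) -> SitePosterior:
    """NEB or BEB per-site posteriors of positive selection.

    NEB applies Bayes' rule across the four site classes at the MLEs.  BEB
    averages the site posteriors over a discrete uniform prior: (p0, p1)
    on a triangle grid, ω0 on (0, 1) and ω2 on (1, ``omega2_prior_max``),
    ``grid_levels`` midpoint levels each, with the remaining parameters
    held at their MLEs.
    """
    if fit.null:
        raise ValueError("site posteriors require the alternative fit")
    work = _ModelAEngine(aln, tree, fit.foreground, fit.codon_freqs)
    lengths = np.append(fit.branch_lengths, 0.0)
    wpat = work.engine.pattern_weights

    if method.upper() == "NEB":
        class_lls = work.class_site_lls(
            fit.kappa, fit.omega0, fit.omega2, lengths, fit.proportions
        )
        logw = np.log(np.maximum(fit.proportions, 1e-300))
        joint = class_lls + logw[:, None]
        norm = logsumexp(joint, axis=0)
        post = np.exp(joint - norm)           # (4, npat)
        p_sel = _expand(work.engine, post[2] + post[3])
        return SitePosterior(
            method="NEB",
            p_selected=p_sel,
            class_posteriors=_expand(work.engine, post).T,
        )

    if method.upper() != "BEB":
        raise ValueError("method must be 'NEB' or 'BEB'")

    d = grid_levels
    w0_grid = (2 * np.arange(d) + 1) / (2 * d)
    w2_grid = 1.0 + (omega2_prior_max - 1.0) * (2 * np.arange(d) + 1) / (2 * d)
    p_grid = [
        ((2 * i + 1) / (2 * d), (2 * j + 1) / (2 * d))
        for i in range(d)
        for j in range(d)
        if (2 * i + 1) / (2 * d) + (2 * j + 1) / (2 * d) <= 1.0 + 1e-12
    ]
    weight_vecs = []
    for p0, p1 in p_grid:
        rest = 1 - p0 - p1
        weight_vecs.append(
            [p0, p1, rest * p0 / (p0 + p1), rest * p1 / (p0 + p1)]
        )
    logw_grid = np.log(np.maximum(np.array(weight_vecs), 1e-300))  # (np_grid, 4)

    npat = work.engine.patterns.shape[1]
    # rate scale fixed at the MLEs (only the grid parameters vary)
    scale = work.scale_factor(fit.kappa, fit.omega0, fit.proportions)
    s1, n1 = _syn_flows(fit.kappa, work.engine._pi)

    def class_ll(w_arr: np.ndarray) -> np.ndarray:
        t_eff = lengths * (s1 + w_arr * n1) / scale
        return work.engine.site_log_likelihoods(fit.kappa, w_arr, t_eff)

    nb = len(work.is_fg)
    ll1 = class_ll(np.ones(nb))
    ll0 = {w0: class_ll(np.full(nb, w0)) for w0 in w0_grid}
    ll2b = {w2: class_ll(np.where(work.is_fg, w2, 1.0)) for w2 in w2_grid}

    n_oo = d * d
    lnls = np.empty((n_oo, len(p_grid)))
    sel_parts = np.empty((n_oo, len(p_grid), npat))
    for a, w0 in enumerate(w0_grid):
        for b, w2 in enumerate(w2_grid):
            ll2a = class_ll(np.where(work.is_fg, w2, w0))
            class_lls = np.stack([ll0[w0], ll1, ll2a, ll2b[w2]])  # (4, npat)
            joint = logw_grid[:, :, None] + class_lls[None, :, :]  # (np, 4, npat)
            site_mix = logsumexp(joint, axis=1)                    # (np, npat)
            c = a * d + b
            lnls[c] = site_mix @ wpat
            sel_parts[c] = np.exp(
                logsumexp(joint[:, 2:, :], axis=1) - site_mix
            )
    flat_lnl = lnls.reshape(-1)
    post_weights = np.exp(flat_lnl - logsumexp(flat_lnl))
    p_sel_pat = post_weights @ sel_parts.reshape(len(flat_lnl), npat)
    return SitePosterior(method="BEB", p_selected=_expand(work.engine, p_sel_pat))


# ---------------------------------------------------------------------------
# reporting


def make_table(fits: list, tests: dict[str, LRTResult] | None = None):
    """Model-comparison table (one row per fit, LRT columns where paired).

    ``tests`` maps a fit's model name to its LRTResult.  Returns a pandas
    DataFrame; use ``.to_csv(..., sep='\\t')`` or ``.to_json`` to persist.
    """
    import pandas as pd

    tests = tests or {}
    rows = []
    for f in fits:
        if isinstance(f, ModelAFit):
            name = ("null" if f.null else "alternative") + " branch-site"
            row = {
                "model": name,
                "minus_lnL": -f.lnL,
                "parameters": (
                    f"p0={f.p0:.3f}, p1={f.p1:.3f} (p2+p3={f.p2_plus_p3:.3f}), "
                    f"w0={f.omega0:.3f}, w1=1, w2={f.omega2:.3f}"
                ),
                "n_free_params": f.n_free_params,
            }
        else:
            omegas = ", ".join(
                f"w{k}={v:.3f}" for k, v in enumerate(f.params.omega_by_class)
            )
            row = {
                "model": f.model_name,
                "minus_lnL": -f.lnL,
                "parameters": f"{omegas}, kappa={f.params.kappa:.3f}",
                "n_free_params": f.n_free_params,
            }
        t = tests.get(row["model"])
        if t is not None:
            row.update({"lrt_statistic": t.statistic, "df": t.df, "p_value": t.p_value})
        rows.append(row)
    return pd.DataFrame(rows)
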