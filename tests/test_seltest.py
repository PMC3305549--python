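import numpy as np
import pytest

from orthosel.codonmodel import fit as gy94_fit
from orthosel.seltest import (
    BranchModelSpec,
    LRTResult,
    branch_site_test,
    fit_branch_model,
    fit_model_a,
    lrt,
    make_table,
    site_posteriors,
)
from orthosel.trees import LabeledTree


class TestLRT:
    def test_equal_likelihoods_give_zero_statistic(self):
        res = lrt(-100.0, -100.0, df=1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_tiny_negative_statistic_clamped(self):
        res = lrt(-100.0, -100.0000001, df=1)
        assert res.statistic == 0.0

    def test_large_negative_statistic_warns(self):
        with pytest.warns(UserWarning, match="clamped"):
            lrt(-100.0, -110.0, df=1)

    def test_known_chi2_quantile(self):
        # 2*Delta = 3.841 is the 5% point of chi2(1)
        res = lrt(-50.0, -50.0 + 3.841459 / 2, df=1)
        assert res.p_value == pytest.approx(0.05, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lrt(np.nan, 0.0, 1)
        with pytest.raises(ValueError):
            lrt(-1.0, -1.0, 0)


class TestBranchModelSpec:
    def test_uncovered_branch_rejected(self, tree8_two_class):
        spec = BranchModelSpec("bad", {0: 0})
        with pytest.raises(ValueError, match="not covered"):
            spec.validate(tree8_two_class)

    def test_non_contiguous_classes_rejected(self, tree8_two_class):
        spec = BranchModelSpec("bad", {0: 0, 1: 2})
        with pytest.raises(ValueError, match="contiguous"):
            spec.validate(tree8_two_class)

    def test_single_class_reduces_to_one_ratio(self, sim_alignment, tree8_two_class):
        aln, _ = sim_alignment(
            tree8_two_class, [(1.0, {0: 0.3, 1: 0.3})], n_codons=100, seed=13
        )
        merged = fit_branch_model(
            aln, tree8_two_class, BranchModelSpec("one", {0: 0, 1: 0}),
            n_starts=1,
        )
        plain = gy94_fit(aln, tree8_two_class, n_omega_classes=1, n_starts=1)
        assert merged.lnL == pytest.approx(plain.lnL, abs=1e-6)
        assert merged.params.omega_by_class.size == 1

    def test_two_class_ordering_recovered(self, sim_alignment, tree8_two_class):
        orderings = []
        for seed in range(6):
            aln, _ = sim_alignment(
                tree8_two_class, [(1.0, {0: 0.2, 1: 0.4})], n_codons=300, seed=seed
            )
            mf = fit_branch_model(
                aln, tree8_two_class, BranchModelSpec("two", {0: 0, 1: 1}),
                n_starts=1,
            )
            w = mf.params.omega_by_class
            orderings.append(w[1] > w[0])
        assert sum(orderings) >= 5

    def test_merging_identical_classes_changes_lnL_little(
        self, sim_alignment, tree8_two_class
    ):
        # both branch classes simulated with the same omega: the extra ratio
        # buys only chi2(1)-level improvements
        stats = []
        for seed in range(8):
            aln, _ = sim_alignment(
                tree8_two_class, [(1.0, {0: 0.3, 1: 0.3})], n_codons=150, seed=seed
            )
            one = gy94_fit(aln, tree8_two_class, n_omega_classes=1, n_starts=1)
            two = fit_branch_model(
                aln, tree8_two_class, BranchModelSpec("two", {0: 0, 1: 1}),
                n_starts=1,
            )
            stats.append(2 * (two.lnL - one.lnL))
        assert np.median(stats) < 3.84
        assert sum(s < 6.63 for s in stats) >= 7


@pytest.fixture(scope="module")
def power_data(tree8_foreground_stem):
    from orthosel.simulate import (
        SimRegime,
        simulate_codon_alignment,
        uniform_codon_freqs,
    )

    regime = SimRegime(
        tree=tree8_foreground_stem,
        kappa=2.0,
        codon_freqs=uniform_codon_freqs(),
        site_classes=[
            (0.5, {0: 0.2, 1: 0.2}),
            (0.4, {0: 1.0, 1: 1.0}),
            (0.05, {0: 0.2, 1: 8.0}),
            (0.05, {0: 1.0, 1: 8.0}),
        ],
        n_codons=500,
        seed=3,
        scaling="shared",
    )
    return simulate_codon_alignment(regime)


@pytest.fixture(scope="module")
def power_result(power_data, tree8_foreground_stem):
    aln, _ = power_data
    return branch_site_test(
        aln, tree8_foreground_stem, foreground=1, fix_kappa=True, n_starts=1
    )


class TestModelA:
    def test_class_proportions_sum_to_one(self, power_data, tree8_foreground_stem):
        aln, _ = power_data
        alt = fit_model_a(
            aln, tree8_foreground_stem, foreground=1, null=False,
            fix_kappa=True, n_starts=1,
        )
        assert alt.proportions.sum() == pytest.approx(1.0)
        assert alt.omega1 == 1.0
        assert 0 < alt.omega0 <= 1.0
        assert alt.omega2 >= 1.0

    def test_null_fixes_omega2(self, power_data, tree8_foreground_stem):
        aln, _ = power_data
        null = fit_model_a(
            aln, tree8_foreground_stem, foreground=1, null=True,
            fix_kappa=True, n_starts=1,
        )
        assert null.omega2 == 1.0
        assert null.n_free_params == 3

    def test_foreground_must_exist_and_leave_background(
        self, power_data, tree8_foreground_stem
    ):
        aln, _ = power_data
        with pytest.raises(ValueError, match="not found"):
            fit_model_a(aln, tree8_foreground_stem, foreground=7)
        with pytest.raises(ValueError, match="background"):
            fit_model_a(aln, tree8_foreground_stem, foreground={0, 1})

    def test_alternative_detects_planted_selection(self, power_result):
        res = power_result
        assert res.alt_fit.lnL >= res.null_fit.lnL
        assert res.alt_fit.omega2 > 1.0
        assert res.test.p_value < 0.05


class TestSitePosteriors:
    def test_neb_class_posteriors_normalized(
        self, power_data, power_result, tree8_foreground_stem
    ):
        aln, _ = power_data
        res = power_result
        neb = site_posteriors(res.alt_fit, aln, tree8_foreground_stem, "NEB")
        assert np.abs(neb.class_posteriors.sum(axis=1) - 1).max() < 1e-10
        assert np.all((neb.p_selected >= 0) & (neb.p_selected <= 1))

    def test_beb_discriminates_true_selected_sites(
        self, power_data, power_result, tree8_foreground_stem
    ):
        aln, site_classes = power_data
        res = power_result
        beb = site_posteriors(res.alt_fit, aln, tree8_foreground_stem, "BEB")
        selected = np.isin(site_classes, [2, 3])
        assert np.all(beb.p_selected <= 1.0)
        assert beb.p_selected[selected].mean() > beb.p_selected[~selected].mean()

    def test_beb_invariant_to_site_order(
        self, power_data, power_result, tree8_foreground_stem
    ):
        from orthosel.codonalign import CodonAlignment

        aln, _ = power_data
        res = power_result
        beb = site_posteriors(res.alt_fit, aln, tree8_foreground_stem, "BEB")
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.length)
        shuffled = CodonAlignment(
            list(aln.names),
            ["".join(r[3 * k : 3 * k + 3] for k in perm) for r in aln.rows],
        )
        beb2 = site_posteriors(res.alt_fit, shuffled, tree8_foreground_stem, "BEB")
        assert np.allclose(beb2.p_selected, beb.p_selected[perm], atol=1e-10)

    def test_no_signal_on_identical_sequences(self, tree8_foreground_stem, uniform_pi):
        from orthosel.codonalign import CodonAlignment
        from orthosel.seltest import ModelAFit

        row = "ATGAAACCCGGGTTTGCA" * 5
        aln = CodonAlignment(
            list(tree8_foreground_stem.leaf_names),
            [row] * tree8_foreground_stem.n_leaves,
        )
        fit = ModelAFit(
            p0=0.7, p1=0.3, omega0=0.2, omega2=5.0, kappa=2.0, lnL=0.0,
            null=False, foreground={1},
            branch_lengths=np.full(
                len(tree8_foreground_stem.postorder()) - 1, 1e-6
            ),
            codon_freqs=uniform_pi, n_free_params=4,
        )
        beb = site_posteriors(fit, aln, tree8_foreground_stem, "BEB")
        assert np.all(beb.p_selected < 0.5)

    def test_null_fit_rejected(self, power_data, tree8_foreground_stem):
        aln, _ = power_data
        null = fit_model_a(
            aln, tree8_foreground_stem, foreground=1, null=True,
            fix_kappa=True, n_starts=1,
        )
        with pytest.raises(ValueError, match="alternative"):
            site_posteriors(null, aln, tree8_foreground_stem, "BEB")


class TestMakeTable:
    def test_single_fit_row(self, sim_alignment):
        tree = LabeledTree.from_newick("(a:0.2,b:0.2,c:0.2);")
        aln, _ = sim_alignment(tree, [(1.0, {0: 0.3})], n_codons=60, seed=1)
        one = gy94_fit(aln, tree, n_omega_classes=1, n_starts=1)
        df = make_table([one])
        assert len(df) == 1
        assert "lrt_statistic" not in df.columns or df["lrt_statistic"].isna().all()

    def test_nested_pair_reports_test(self, sim_alignment, tree8_two_class):
        aln, _ = sim_alignment(
            tree8_two_class, [(1.0, {0: 0.2, 1: 0.5})], n_codons=80, seed=3
        )
        one = gy94_fit(aln, tree8_two_class, n_omega_classes=1, n_starts=1)
        two = fit_branch_model(
            aln, tree8_two_class, BranchModelSpec("two-ratio", {0: 0, 1: 1}),
            n_starts=1,
        )
        test = lrt(one.lnL, two.lnL, df=1)
        df = make_table([one, two], {"two-ratio": test})
        row = df[df["model"] == "two-ratio"].iloc[0]
        assert row["df"] == 1
        assert row["lrt_statistic"] == pytest.approx(test.statistic)
        # round trip through JSON preserves the values
        import pandas as pd, io

        back = pd.read_json(io.StringIO(df.to_json()))
        assert back["minus_lnL"].tolist() == pytest.approx(df["minus_lnL"].tolist())
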