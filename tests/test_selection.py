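"""LRT, FDR, consensus, and the model fits on small simulated data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hlscan as h
from hlscan.selection import ModelAEvaluator, branch_site_loglik, m0_loglik
from hlscan.simulate import M0Params, simulate_alignment
from hlscan.tree import parse_newick


class TestLRT:
    def test_equal_likelihoods(self):
        stat, p = h.lrt(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, p = h.lrt(-100.0, -100.0 + 1.9207)
        assert stat == pytest.approx(3.8414, abs=1e-3)
        assert p == pytest.approx(0.0500, abs=1e-3)

    def test_negative_difference_clamped(self):
        stat, p = h.lrt(-100.0, -100.0001)
        assert stat == 0.0 and p == 1.0

    def test_boundary_mixture_halves_p(self):
        _, p_plain = h.lrt(-100.0, -98.0)
        _, p_mix = h.lrt(-100.0, -98.0, boundary_mixture=True)
        assert p_mix == pytest.approx(p_plain / 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            h.lrt(float("nan"), -1.0)


def bh_oracle(p):
    """Quadratic-time step-up: q_i = min over j with p_j >= p_i of
    m * p_j / rank(p_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * ranked[i] / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhFdr:
    def test_single_p(self):
        assert h.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        q = h.bh_fdr([0.002, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.008, 0.02, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(h.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h.bh_fdr([0.5, 1.5])

    def test_empty_input(self):
        assert h.bh_fdr([]).size == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_bruteforce_and_dominates_p(self, ps):
        q = h.bh_fdr(ps)
        assert np.allclose(q, bh_oracle(ps), atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(h.bh_fdr(p)[perm], h.bh_fdr(p[perm]))


def record(gene, p, q):
    return h.GeneTestRecord(gene_id=gene, lnL_null=0, lnL_alt=0, lrt_stat=0,
                            p_value=p, q_value=q, params_alt=None,
                            params_null=None, n_sites=0, n_taxa=0)


class TestConsensus:
    def test_significant_under_both_retained(self):
        res = {"m1": [record("g", 0.001, 0.01)],
               "m2": [record("g", 0.002, 0.02)]}
        assert h.consensus(res, alpha=0.05) == {"g"}

    def test_significant_under_one_dropped(self):
        res = {"m1": [record("g", 0.001, 0.01)],
               "m2": [record("g", 0.5, 0.8)]}
        assert h.consensus(res, alpha=0.05) == set()

    def test_empty_inputs(self):
        assert h.consensus({"m1": [], "m2": []}) == set()
        with pytest.raises(ValueError):
            h.consensus({})

    def test_p_value_mode(self):
        res = {"m1": [record("g", 0.01, 0.2)]}
        assert h.consensus(res, alpha=0.05, use_q=False) == {"g"}
        assert h.consensus(res, alpha=0.05, use_q=True) == set()


class TestBranchSiteParams:
    def test_weights_sum_to_one(self):
        p = h.BranchSiteParams(2.0, 0.2, 3.0, 0.6, 0.3,
                               pi=h.CodonFrequencies.uniform())
        assert p.weights().sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kw", [
        dict(omega0=1.5), dict(omega2=0.5), dict(p0=0.8, p1=0.4),
        dict(p0=0.0, p1=0.0),
    ])
    def test_invalid_domains_rejected(self, kw):
        base = dict(kappa=2.0, omega0=0.2, omega2=3.0, p0=0.6, p1=0.3,
                    pi=h.CodonFrequencies.uniform())
        base.update(kw)
        with pytest.raises(ValueError):
            h.BranchSiteParams(**base)


@pytest.fixture(scope="module")
def six_taxon_setup(uniform_pi):
    tree = parse_newick(
        "(((A:0.1,B:0.15):0.08,(C:0.2,D:0.12):0.06):0.25 #1,E:0.2,F:0.3);")
    aln, _ = simulate_alignment(tree, "M0", M0Params(2.0, 0.3, uniform_pi),
                                120, seed=31)
    return tree, aln


class TestFitM0:
    def test_identical_sequences_drive_lengths_to_bound(self, uniform_pi):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        code = h.standard_code()
        rng = np.random.default_rng(5)
        row = rng.integers(0, 61, size=30)
        aln = h.CodonAlignment(taxa=["A", "B", "C"],
                               sites=np.vstack([row, row, row]))
        fit = h.fit_m0(aln, tree)
        assert max(fit.branch_lengths) < 1e-4

    def test_refit_is_fixed_point(self, six_taxon_setup):
        tree, aln = six_taxon_setup
        fit = h.fit_m0(aln, tree)
        refit = h.fit_m0(aln, fit.tree, kappa_init=fit.kappa,
                         omega_init=fit.omega)
        assert refit.lnL == pytest.approx(fit.lnL, abs=1e-4)

    def test_lnl_matches_direct_evaluation(self, six_taxon_setup):
        tree, aln = six_taxon_setup
        fit = h.fit_m0(aln, tree)
        direct = m0_loglik(aln, fit.tree, fit.kappa, fit.omega, pi=fit.pi)
        assert direct == pytest.approx(fit.lnL, abs=1e-8)

    def test_single_taxon_rejected(self, uniform_pi):
        aln = h.CodonAlignment(taxa=["A"], sites=np.zeros((1, 3), dtype=int))
        with pytest.raises(ValueError):
            h.fit_m0(aln, parse_newick("A:0.1;"))


class TestBranchSiteFit:
    def test_boundary_reduces_to_one_ratio(self, six_taxon_setup, uniform_pi):
        """With p0=1 the mixture collapses to a single class with omega0 on
        every branch, which is exactly the one-ratio likelihood."""
        tree, aln = six_taxon_setup
        pi = h.estimate_codon_frequencies(aln)
        params = h.BranchSiteParams(2.0, 0.3, 2.0, p0=1.0, p1=0.0, pi=pi)
        mixture = branch_site_loglik(aln, tree, params)
        one_ratio = m0_loglik(aln, tree, 2.0, 0.3, pi=pi)
        assert mixture == pytest.approx(one_ratio, abs=1e-6)

    def test_nesting_on_null_data(self, six_taxon_setup):
        tree, aln = six_taxon_setup
        pi = h.estimate_codon_frequencies(aln)
        ev = ModelAEvaluator(aln, tree, pi)
        _, lnl_null = h.fit_branch_site(aln, tree, null=True, pi=pi,
                                        n_starts=1, evaluator=ev)
        _, lnl_alt = h.fit_branch_site(aln, tree, null=False, pi=pi,
                                       n_starts=1, evaluator=ev)
        assert lnl_alt >= lnl_null - 1e-6
        stat, p = h.lrt(lnl_null, lnl_alt)
        assert 0 <= p <= 1

    def test_empty_foreground_rejected(self, uniform_pi):
        tree = parse_newick("(A:0.1,B:0.1);")
        aln, _ = simulate_alignment(tree, "M0",
                                    M0Params(2.0, 0.3, uniform_pi), 10, seed=1)
        with pytest.raises(ValueError, match="foreground"):
            h.fit_branch_site(aln, tree)

    def test_evaluator_general_path_matches_oneshot(self, uniform_pi):
        """Foreground on a deep internal branch disables the shared-subtree
        fast path; both code paths must agree with the one-shot reference."""
        tree = parse_newick(
            "((((A:0.1,B:0.15):0.2 #1,C:0.2):0.1,D:0.12):0.05,E:0.3,F:0.2);")
        aln, _ = simulate_alignment(tree, "M0",
                                    M0Params(2.0, 0.3, uniform_pi), 60,
                                    seed=33)
        pi = h.estimate_codon_frequencies(aln)
        params = h.BranchSiteParams(2.2, 0.15, 4.5, 0.55, 0.3, pi=pi)
        ev = ModelAEvaluator(aln, tree, pi)
        assert not ev._fg_at_root
        stacked = ev.class_ll(2.2, 0.15, 4.5, weights=params.weights())
        from hlscan.likelihood import PruningEngine
        from hlscan.selection import class_site_logliks
        eng = PruningEngine(aln, tree)
        oneshot = class_site_logliks(eng, tree, 2.2, 0.15, 4.5, pi,
                                     weights=params.weights())
        assert np.abs(ev.engine.expand(stacked) - oneshot).max() < 1e-10

    def test_evaluator_matches_oneshot(self, six_taxon_setup):
        tree, aln = six_taxon_setup
        pi = h.estimate_codon_frequencies(aln)
        params = h.BranchSiteParams(1.8, 0.25, 3.5, 0.6, 0.25, pi=pi)
        ev = ModelAEvaluator(aln, tree, pi)
        stacked = ev.class_ll(1.8, 0.25, 3.5, weights=params.weights())
        from hlscan.likelihood import PruningEngine
        from hlscan.selection import class_site_logliks
        eng = PruningEngine(aln, tree)
        oneshot = class_site_logliks(eng, tree, 1.8, 0.25, 3.5, pi,
                                     weights=params.weights())
        assert np.abs(ev.engine.expand(stacked) - oneshot).max() < 1e-10
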