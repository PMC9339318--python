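"""Exact latent branch-state marginalization, Bayes factors, subscale LRT."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from owlaccel.alignments import ElementAlignment
from owlaccel.errors import DataError, InvalidParameterError
from owlaccel.phylo import prune_loglik
from owlaccel.rateshift import (RateShiftConfig, RateShiftResult,
                                SubscaleResult, add_subscale_fdr,
                                branch_state_prior, call_candidate,
                                fit_rate_shift, fit_subscale_lrt,
                                latent_marginal_loglik,
                                summarize_subscale_by_length,
                                _config_dp, _config_logliks)
from owlaccel.simulate import RegimeSpec, simulate_alignment
from owlaccel.trees import Phylogeny


def brute_force_states(tree, cfg, gtr, aln, r1, r2):
    """Enumerate admissible branch-state vectors directly (oracle)."""
    logphi = branch_state_prior(cfg, tree)
    branches = [int(b) for b in tree.branches]
    terms, vectors = [], []
    for zvec in itertools.product(range(3), repeat=len(branches)):
        z = dict(zip(branches, zvec))
        lp = 0.0
        for b in branches:
            par = int(tree.parent[b])
            zp = 0 if par == tree.root else z[par]
            lp += logphi[b, zp, z[b]]
        if not np.isfinite(lp):
            continue
        mult = {b: (1.0, r1, r2)[z[b]] for b in branches}
        ll = prune_loglik(tree, aln, gtr, branch_multipliers=mult)
        terms.append(lp + ll)
        vectors.append(z)
    return np.array(terms), vectors


def _rand_aln(tree, seed, length=30):
    rng = np.random.default_rng(seed)
    return ElementAlignment("x", {
        n: "".join(rng.choice(list("ACGT"), length)) for n in tree.tip_names})


class TestLatentMarginal:
    @pytest.mark.parametrize("model_name", ["M0", "M1", "M2"])
    def test_matches_brute_force(self, tree5, model5, gtr, model_name):
        aln = _rand_aln(tree5, seed=21)
        cfg = RateShiftConfig.for_model(tree5, model_name)
        fast = latent_marginal_loglik(aln, model5, cfg, 0.3, 2.0, tree=tree5)
        terms, _ = brute_force_states(tree5, cfg, gtr, aln, 0.3, 2.0)
        assert abs(fast - logsumexp(terms)) < 1e-8

    def test_matches_brute_force_six_tips(self, gtr):
        tree = Phylogeny.from_newick(
            "(((a:0.1,b:0.15):0.05,(c:0.2,d:0.1):0.08):0.05,"
            "(e:0.25,f:0.12):0.06);", foreground=("a", "c", "e"))
        from owlaccel.phylo import NeutralModel
        model = NeutralModel(gtr, tree)
        aln = _rand_aln(tree, seed=22)
        cfg = RateShiftConfig.for_model(tree, "M1")
        fast = latent_marginal_loglik(aln, model, cfg, 0.4, 1.8, tree=tree)
        terms, _ = brute_force_states(tree, cfg, gtr, aln, 0.4, 1.8)
        assert abs(fast - logsumexp(terms)) < 1e-8

    def test_posteriors_match_enumeration(self, tree5, model5, gtr):
        aln = _rand_aln(tree5, seed=23)
        cfg = RateShiftConfig.for_model(tree5, "M2")
        r1, r2 = 0.3, 2.0
        dp = _config_dp(tree5, cfg)
        ll = _config_logliks(dp, __import__("owlaccel.alignments",
                                            fromlist=["encode_patterns"]
                                            ).encode_patterns(aln, tree5),
                             model5, np.array([[r1, r2]]))[:, 0]
        Z, lp = dp.config_matrix()
        joint = lp + ll
        pp_fast = {b: float(np.exp(logsumexp(joint[Z[:, b] == 2])
                                   - logsumexp(joint)))
                   for b in map(int, tree5.branches)}
        terms, vectors = brute_force_states(tree5, cfg, gtr, aln, r1, r2)
        denom = logsumexp(terms)
        for b in map(int, tree5.branches):
            sel = [t for t, z in zip(terms, vectors) if z[b] == 2]
            pp_brute = np.exp(logsumexp(sel) - denom) if sel else 0.0
            assert abs(pp_fast[b] - pp_brute) < 1e-8

    def test_forced_neutral_identity(self, tree5, model5, gtr):
        # alpha ~ 0 pins every branch neutral: marginal == plain pruning
        aln = _rand_aln(tree5, seed=24)
        cfg = RateShiftConfig(model="M0", allowed=frozenset(), alpha=1e-12,
                              beta=0.2)
        got = latent_marginal_loglik(aln, model5, cfg, 0.9999999, 2.0,
                                     tree=tree5)
        assert abs(got - prune_loglik(tree5, aln, gtr)) < 1e-5

    def test_forced_conserved_identity(self, tree5, model5, gtr):
        # alpha ~ 1 pins every branch conserved: marginal == pruning at r1
        aln = _rand_aln(tree5, seed=25)
        cfg = RateShiftConfig(model="M0", allowed=frozenset(),
                              alpha=1 - 1e-12, beta=0.2)
        r1 = 0.3
        got = latent_marginal_loglik(aln, model5, cfg, r1, 2.0, tree=tree5)
        mult = {int(b): r1 for b in tree5.branches}
        want = prune_loglik(tree5, aln, gtr, branch_multipliers=mult)
        assert abs(got - want) < 1e-5

    def test_rate_order_enforced(self, tree5, model5):
        aln = _rand_aln(tree5, seed=26)
        cfg = RateShiftConfig.for_model(tree5, "M1")
        with pytest.raises(InvalidParameterError):
            latent_marginal_loglik(aln, model5, cfg, 0.5, 0.4, tree=tree5)

    def test_max_config_monotone_in_allowed_set(self, tree5, model5):
        # nested allowed sets: the best single configuration can only improve
        aln = _rand_aln(tree5, seed=27)
        from owlaccel.alignments import encode_patterns
        pat = encode_patterns(aln, tree5)
        grid = np.array([[0.3, 2.0]])
        best = []
        for name in ("M0", "M1", "M2"):
            cfg = RateShiftConfig.for_model(tree5, name)
            dp = _config_dp(tree5, cfg)
            ll = _config_logliks(dp, pat, model5, grid)[:, 0]
            best.append(ll.max())
        assert best[0] <= best[1] + 1e-9 <= best[2] + 2e-9


class TestBayesFactors:
    def test_bf2_is_logml_difference(self, owl_tree, neutral):
        aln = simulate_alignment(owl_tree, neutral,
                                 RegimeSpec.conserved(owl_tree, 0.3, 120, 1),
                                 seed=31)[0]
        r = fit_rate_shift(aln, neutral, min_length=50)
        assert r.logbf1 == r.logml["M1"] - r.logml["M0"]
        assert r.logbf2 == r.logml["M1"] - r.logml["M2"]

    def test_short_element_skipped(self, owl_tree, neutral):
        aln = simulate_alignment(owl_tree, neutral,
                                 RegimeSpec.conserved(owl_tree, 0.3, 40, 1),
                                 seed=32)[0]
        with pytest.raises(DataError):
            fit_rate_shift(aln, neutral)


class TestCandidateRule:
    def _result(self, owl_tree, bf1, bf2, pp):
        names = sorted(owl_tree.foreground_names)
        pp_map = {n: p for n, p in zip(names, pp)}
        for b in owl_tree.branches:
            pp_map.setdefault(owl_tree.names[int(b)] or f"node{int(b)}", 0.0)
        return RateShiftResult(element="e", logml={}, logbf1=bf1, logbf2=bf2,
                               pp_m2=pp_map, pp_m1=pp_map, r1_hat=0.3,
                               r2_hat=2.0)

    def test_passing_case(self, owl_tree):
        r = self._result(owl_tree, 12.0, 1.5, (0.9, 0.85, 0.3))
        assert call_candidate(r, owl_tree)

    def test_bf1_boundary(self, owl_tree):
        assert call_candidate(self._result(owl_tree, 10.0, 1.5,
                                           (0.9, 0.85, 0.3)), owl_tree)
        assert not call_candidate(self._result(owl_tree, 9.9, 1.5,
                                               (0.9, 0.85, 0.3)), owl_tree)

    def test_two_of_three_required(self, owl_tree):
        assert not call_candidate(self._result(owl_tree, 12.0, 1.5,
                                               (0.95, 0.5, 0.5)), owl_tree)

    def test_bf2_boundary(self, owl_tree):
        assert not call_candidate(self._result(owl_tree, 12.0, 0.99,
                                               (0.9, 0.85, 0.9)), owl_tree)


class TestSubscale:
    def test_recovery_direction_and_nesting(self, owl_tree, neutral):
        spec = RegimeSpec("fg2", {int(b): (2.0 if b in owl_tree.foreground
                                           else 1.0)
                                  for b in owl_tree.branches}, 500, 1)
        aln = simulate_alignment(owl_tree, neutral, spec, seed=41)[0]
        r = fit_subscale_lrt(aln, neutral)
        assert r.lnl_alt >= r.lnl_null
        assert r.subscale > 1.2

    def test_all_missing_rejected(self, owl_tree, neutral):
        aln = ElementAlignment("x", {n: "N" * 60 for n in owl_tree.tip_names})
        with pytest.raises(DataError):
            fit_subscale_lrt(aln, neutral)

    def test_significance_needs_subscale_above_one(self):
        rows = [SubscaleResult("a", "gene", 300, 1, 0.5, 1.0, -10, -1,
                               18.0, 1e-5),
                SubscaleResult("b", "gene", 300, 1, 2.0, 1.0, -10, -1,
                               18.0, 1e-5)]
        add_subscale_fdr(rows)
        assert not rows[0].significant   # tiny p but subscale < 1
        assert rows[1].significant

    def test_fdr_within_class(self):
        rows = ([SubscaleResult(f"g{i}", "gene", 300, 1, 2, 1, -10, -1,
                                18.0, 0.5) for i in range(9)]
                + [SubscaleResult("hit", "owl_cnee", 300, 1, 2, 1, -10, -1,
                                  18.0, 0.04)])
        add_subscale_fdr(rows)
        # the lone owl CNEE is corrected only within its own class
        assert rows[-1].q == pytest.approx(0.04)


class TestLengthSummary:
    def _row(self, cls, length, subscale=2.0, sig=True):
        r = SubscaleResult("e", cls, length, 1, subscale, 1.0, -10, -1,
                           18.0, 1e-4)
        r.q, r.significant = 1e-3, sig
        return r

    def test_length_exclusions(self):
        rows = [self._row("gene", 1001), self._row("gene", 900),
                self._row("avian_cnee", 199), self._row("avian_cnee", 250),
                self._row("owl_cnee", 250)]
        table = summarize_subscale_by_length(rows)
        kept = dict(zip(table["element_class"], table["n"]))
        assert kept == {"gene": 1, "avian_cnee": 1, "owl_cnee": 1}

    def test_counts_conserved(self):
        rows = [self._row("owl_cnee", 100 + 37 * i) for i in range(12)]
        table = summarize_subscale_by_length(rows)
        assert table["n"].sum() == 12

    def test_only_significant(self):
        rows = [self._row("gene", 500, sig=False)]
        assert summarize_subscale_by_length(rows).empty
        assert len(summarize_subscale_by_length(rows,
                                                only_significant=False)) == 1

    def test_empty_input(self):
        assert summarize_subscale_by_length([]).empty
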