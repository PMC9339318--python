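"""Codon substitution models and selection LRTs."""

import itertools

import numpy as np
import pytest

from owlaccel.codon import (SENSE_CODONS, CodonAlignment, CodonModel,
                            apply_fdr, build_codon_matrix, codon_loglik,
                            fit_branch_model, fit_branch_site_model,
                            multiple_test_correct, per_branch_foreground_test,
                            _PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN)
from owlaccel.errors import DataError, InvalidParameterError
from owlaccel.simulate import simulate_codon_alignment
from owlaccel.trees import Phylogeny


@pytest.fixture(scope="module")
def uniform61():
    return np.full(61, 1.0 / 61)


class TestCodonMatrix:
    def test_dimension(self, uniform61):
        assert build_codon_matrix(2.0, 0.5, uniform61).shape == (61, 61)
        assert len(SENSE_CODONS) == 61

    def test_rows_sum_to_zero(self, uniform61):
        Q = build_codon_matrix(3.0, 0.2, uniform61)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-(uniform61 * np.diag(Q)).sum(), 1.0)

    def test_neutral_equal_rates_proportional_to_target(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = build_codon_matrix(1.0, 1.0, pi)
        rates = Q[_PAIR_I, _PAIR_J] / pi[_PAIR_J]
        assert np.allclose(rates, rates[0])

    def test_synonymous_ts_tv_ratio_is_kappa(self, uniform61):
        kappa = 3.7
        Q = build_codon_matrix(kappa, 0.4, uniform61)
        syn_ts = Q[_PAIR_I, _PAIR_J][_PAIR_SYN & _PAIR_TS]
        syn_tv = Q[_PAIR_I, _PAIR_J][_PAIR_SYN & ~_PAIR_TS]
        assert np.isclose(syn_ts[0] / syn_tv[0], kappa)

    def test_multi_nucleotide_changes_zero(self, uniform61):
        Q = build_codon_matrix(2.0, 0.5, uniform61)
        multi = np.ones((61, 61), dtype=bool)
        np.fill_diagonal(multi, False)
        multi[_PAIR_I, _PAIR_J] = False
        assert np.all(Q[multi] == 0.0)

    @pytest.mark.parametrize("kappa,omega", [(-1, 0.5), (0, 0.5), (2, -0.5)])
    def test_invalid_parameters(self, kappa, omega, uniform61):
        with pytest.raises(InvalidParameterError):
            build_codon_matrix(kappa, omega, uniform61)


class TestCodonPruning:
    def test_matches_enumeration(self, uniform61):
        tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,c:0.25);",
                                     foreground=("a",))
        aln = simulate_codon_alignment(
            tree, kappa=2.0, omega_map={"foreground": 1.5, "background": 0.3},
            n_codons=5, seed=9)
        kappa, w_bg, w_fg, scale = 1.7, 0.4, 2.0, 0.9
        fast = codon_loglik(aln, tree, kappa, w_bg, w_fg, scale=scale,
                            freqs=uniform61)
        m_bg = CodonModel(kappa, w_bg, uniform61)
        m_fg = CodonModel(kappa, w_fg, uniform61)
        a_i = tree.tip_index("a")
        P = {}
        for b in tree.branches:
            b = int(b)
            m = m_fg if b == a_i else m_bg
            P[b] = m.transitions(np.array([tree.lengths[b] * scale]))[0]
        from owlaccel.codon import CODON_INDEX
        internal = [i for i in range(tree.n_nodes) if tree.children(i)]
        total = 0.0
        for c in range(aln.n_codons):
            obs = {tree.tip_index(t): CODON_INDEX[aln.seqs[t][3*c:3*c+3]]
                   for t in aln.taxa}
            site = 0.0
            for assign in itertools.product(range(61), repeat=len(internal)):
                st = dict(zip(internal, assign))
                st.update(obs)
                p = uniform61[st[tree.root]]
                for b in tree.branches:
                    b = int(b)
                    p *= P[b][st[int(tree.parent[b])], st[b]]
                site += p
            total += np.log(site)
        assert abs(fast - total) < 1e-6

    def test_column_order_invariance(self, owl_tree):
        aln = simulate_codon_alignment(
            owl_tree, kappa=2.0,
            omega_map={"foreground": 2.0, "background": 0.2},
            n_codons=60, seed=12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_codons)
        shuffled = CodonAlignment(aln.id, {
            t: "".join(s[3*i:3*i+3] for i in perm)
            for t, s in aln.seqs.items()})
        r1 = fit_branch_model(aln, owl_tree)
        r2 = fit_branch_model(shuffled, owl_tree)
        assert np.isclose(r1.lrt, r2.lrt, atol=1e-6)
        assert np.isclose(r1.lnL_alt, r2.lnL_alt, atol=1e-6)

    def test_foreground_everywhere_collapses_to_null(self, owl_tree):
        aln = simulate_codon_alignment(
            owl_tree, kappa=2.0,
            omega_map={"foreground": 0.3, "background": 0.3},
            n_codons=50, seed=13)
        res = fit_branch_model(aln, owl_tree,
                               foreground=frozenset(int(b) for b
                                                    in owl_tree.branches))
        assert res.lnL_alt - res.lnL_null < 1e-6


class TestBranchModels:
    def test_branch_model_detects_contrast(self, owl_tree):
        aln = simulate_codon_alignment(
            owl_tree, kappa=2.0,
            omega_map={"foreground": 2.0, "background": 0.2},
            n_codons=300, seed=100)
        r = fit_branch_model(aln, owl_tree)
        assert r.lnL_alt >= r.lnL_null
        assert r.omega_foreground > r.omega_background
        assert r.p < 0.05

    def test_branch_site_nesting_and_signal_ordering(self, owl_tree):
        # the branch-site LRT separates planted foreground-site selection
        # from null data, even though its absolute power is modest on the
        # short diurnal tip branches of this design
        lrt_sig, lrt_null, hits_sig = [], [], 0
        for s in range(6):
            sig = simulate_codon_alignment(
                owl_tree, kappa=2.0,
                omega_map={"foreground": None, "background": None},
                n_codons=300, seed=200 + s,
                site_classes=[(0.9, 0.2, 0.2), (0.1, 4.0, 0.2)])
            null = simulate_codon_alignment(
                owl_tree, kappa=2.0,
                omega_map={"foreground": 0.2, "background": 0.2},
                n_codons=300, seed=300 + s)
            r_sig = fit_branch_site_model(sig, owl_tree)
            r_null = fit_branch_site_model(null, owl_tree)
            assert r_sig.lnL_alt >= r_sig.lnL_null
            assert r_null.lnL_alt >= r_null.lnL_null
            lrt_sig.append(r_sig.lrt)
            lrt_null.append(r_null.lrt)
            hits_sig += r_sig.p < 0.05
        assert np.mean(lrt_sig) > np.mean(lrt_null)
        assert hits_sig >= 2

    def test_per_branch_planted_foreground(self, owl_tree):
        # selection on exactly two diurnal tips -> foreground specific
        aln = simulate_codon_alignment(
            owl_tree, kappa=2.0,
            omega_map={"foreground": 0.2, "background": 0.2,
                       "nodes": {"snowy_owl": 4.0, "hawk_owl": 4.0}},
            n_codons=400, seed=77)
        rows = per_branch_foreground_test(aln, owl_tree, [aln.id])
        assert rows and all(r.foreground_specific for r in rows)

    def test_per_branch_nocturnal_signal_rejected(self, owl_tree):
        aln = simulate_codon_alignment(
            owl_tree, kappa=2.0,
            omega_map={"foreground": 0.2, "background": 0.2,
                       "nodes": {"snowy_owl": 4.0, "hawk_owl": 4.0,
                                 "eagle_owl": 4.0}},
            n_codons=400, seed=78)
        rows = per_branch_foreground_test(aln, owl_tree, [aln.id])
        assert rows and not any(r.foreground_specific for r in rows)

    def test_empty_candidate_list(self, owl_tree):
        assert per_branch_foreground_test({}, owl_tree, []) == []


class TestMultipleTesting:
    def test_holm_hand_computation(self):
        adj = multiple_test_correct([0.001, 0.04], method="holm")
        assert np.allclose(adj, [0.002, 0.04])

    def test_bh_hand_computation(self):
        adj = multiple_test_correct([0.01, 0.02, 0.03, 0.04], method="BH")
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        for method in ("BH", "holm"):
            assert np.all(multiple_test_correct(p, method) >= p - 1e-12)

    def test_single_p_unchanged(self):
        for method in ("BH", "holm"):
            assert np.isclose(multiple_test_correct([0.123], method)[0], 0.123)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            multiple_test_correct([0.5, 1.2])
        with pytest.raises(InvalidParameterError):
            multiple_test_correct([0.5, -0.1], method="holm")

    def test_apply_fdr_requires_omega_contrast(self, owl_tree):
        from owlaccel.codon import SelectionTestResult
        rows = [SelectionTestResult("g1", "branch", -10, -1, 0.5, 0.1,
                                    18.0, 1, 1e-5),
                SelectionTestResult("g2", "branch", -10, -1, 0.1, 0.9,
                                    18.0, 1, 1e-5)]
        apply_fdr(rows)
        assert not rows[0].accelerated      # significant but w_fg < w_bg
        assert rows[1].accelerated


def test_stop_codons_masked():
    aln = CodonAlignment("g", {"a": "TAAGGA", "b": "GGAGGC"})
    tree = Phylogeny.from_newick("(a:0.1,b:0.1);")
    from owlaccel.codon import encode_codon_patterns
    pat = encode_codon_patterns(aln, tree)
    # the TAA stop in taxon a must be encoded as missing
    col = pat.codes[:, pat.pattern_of_column[0]]
    assert col[tree.tip_index("a")] == 61


def test_all_missing_gene_rejected(owl_tree):
    aln = CodonAlignment("g", {n: "---NNN" for n in owl_tree.tip_names})
    with pytest.raises(DataError):
        fit_branch_model(aln, owl_tree)
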