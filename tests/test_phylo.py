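"""Substitution-model and pruning-likelihood correctness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owlaccel.alignments import ElementAlignment
from owlaccel.errors import (AlignmentTreeMismatchError, DataError, FrameError,
                             InvalidParameterError)
from owlaccel.phylo import (GTRModel, build_rate_matrix, extract_4d_sites,
                            fit_neutral_model, prune_loglik,
                            transition_matrix)
from owlaccel.simulate import RegimeSpec, simulate_alignment
from owlaccel.trees import Phylogeny


def brute_force_loglik(tree, aln, model, multipliers=None):
    """Exhaustive sum over internal-node states (independent oracle)."""
    mult = {int(b): 1.0 for b in tree.branches}
    if multipliers:
        mult.update({int(k): v for k, v in multipliers.items()})
    P = {int(b): transition_matrix(model.Q, tree.lengths[int(b)]
                                   * mult[int(b)]) for b in tree.branches}
    internal = [i for i in range((tree.n_nodes)) if tree.children(i)]
    total = 0.0
    length = aln.length
    for col in range(length):
        obs = {}
        for name, seq in aln.seqs.items():
            base = seq[col]
            obs[tree.tip_index(name)] = ("ACGT".index(base)
                                         if base in "ACGT" else None)
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = dict(zip(internal, assign))
            prob = model.pi[state[tree.root]]
            ok = True
            for b in tree.branches:
                b = int(b)
                parent_state = state[int(tree.parent[b])]
                own = state.get(b, obs.get(b))
                if own is None:   # missing tip: marginalize
                    continue
                prob *= P[b][parent_state, own]
            # tips with missing data contribute a factor of 1 (skipped)
            site += prob if ok else 0.0
        total += np.log(site)
    return total


class TestRateMatrix:
    def test_jukes_cantor_shape(self):
        Q = build_rate_matrix(np.ones(6), np.full(4, 0.25))
        assert np.allclose(Q[~np.eye(4, dtype=bool)], 1.0 / 3.0)
        assert np.allclose(np.diag(Q), -1.0)

    @given(st.lists(st.floats(0.1, 10), min_size=6, max_size=6),
           st.lists(st.floats(0.05, 1), min_size=4, max_size=4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_generator_invariants(self, exch, freqs):
        pi = np.array(freqs) / np.sum(freqs)
        Q = build_rate_matrix(np.array(exch), pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-(pi * np.diag(Q)).sum(), 1.0)
        # detailed balance
        flow = pi[:, None] * Q
        assert np.allclose(flow, flow.T, atol=1e-12)

    @pytest.mark.parametrize("exch,freqs", [
        (np.array([1, 1, 1, 1, 1, -1.0]), np.full(4, 0.25)),
        (np.ones(6), np.array([0.5, 0.5, 0.25, -0.25])),
        (np.ones(6), np.array([0.3, 0.3, 0.3, 0.3])),
    ])
    def test_invalid_parameters(self, exch, freqs):
        with pytest.raises(InvalidParameterError):
            build_rate_matrix(exch, freqs)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, gtr):
        assert np.allclose(transition_matrix(gtr, 0.0), np.eye(4))

    def test_jc_closed_form(self):
        jc = GTRModel.jukes_cantor()
        P = transition_matrix(jc, 0.3)
        same = 0.25 + 0.75 * np.exp(-4.0 * 0.3 / 3.0)
        assert np.allclose(np.diag(P), same, atol=1e-10)
        assert np.allclose(P[~np.eye(4, dtype=bool)], (1 - same) / 3,
                           atol=1e-10)

    def test_rows_stochastic(self, gtr):
        for t in (0.01, 0.3, 2.5, 40.0):
            P = transition_matrix(gtr, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0 and P.max() <= 1

    def test_chapman_kolmogorov(self, gtr):
        t1, t2 = 0.17, 0.45
        lhs = transition_matrix(gtr, t1 + t2)
        rhs = transition_matrix(gtr, t1) @ transition_matrix(gtr, t2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_negative_time_rejected(self, gtr):
        with pytest.raises(InvalidParameterError):
            transition_matrix(gtr, -0.1)


class TestPruning:
    def test_zero_lengths_single_column(self, gtr):
        tree = Phylogeny.from_newick("((a:0,b:0):0,c:0);")
        aln = ElementAlignment("x", {"a": "A", "b": "A", "c": "A"})
        assert np.isclose(prune_loglik(tree, aln, gtr),
                          np.log(gtr.pi[0]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration(self, gtr, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 6))
        names = [chr(ord("a") + i) for i in range(n_tips)]
        newick = names[0] + ":0.1"
        for name in names[1:]:
            newick = f"({newick},{name}:{rng.uniform(0.05, 0.4):.3f})" \
                     f":{rng.uniform(0.02, 0.2):.3f}"
        tree = Phylogeny.from_newick(newick + ";")
        seqs = {n: "".join(rng.choice(list("ACGTN-"), 10,
                                      p=[.22, .22, .22, .22, .06, .06]))
                for n in names}
        aln = ElementAlignment("x", seqs)
        fast = prune_loglik(tree, aln, gtr)
        brute = brute_force_loglik(tree, aln, gtr)
        assert abs(fast - brute) < 1e-8

    def test_all_missing_column_contributes_zero(self, gtr):
        tree = Phylogeny.from_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        base = ElementAlignment("x", {"a": "ACGT", "b": "AAGT", "c": "ACTT"})
        padded = ElementAlignment("x", {"a": "ACGTN", "b": "AAGT-",
                                        "c": "ACTTN"})
        assert np.isclose(prune_loglik(tree, base, gtr),
                          prune_loglik(tree, padded, gtr))

    def test_scaling_equals_uniform_multiplier(self, gtr, owl_tree, neutral):
        aln = simulate_alignment(owl_tree, neutral,
                                 RegimeSpec.neutral(length=50, count=1),
                                 seed=3)[0]
        s = 0.37
        scaled = owl_tree.scaled(s)
        mult = {int(b): s for b in owl_tree.branches}
        assert np.isclose(prune_loglik(scaled, aln, gtr),
                          prune_loglik(owl_tree, aln, gtr,
                                       branch_multipliers=mult), atol=1e-9)

    def test_reroot_invariance(self, gtr):
        # same unrooted topology and path lengths, different root edges
        t1 = Phylogeny.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1);")
        t2 = Phylogeny.from_newick("(a:0.1,(b:0.2,((c:0.3,d:0.15):0.15)x:0)y:0);")
        t3 = Phylogeny.from_newick("(((a:0.1,b:0.2):0.15,c:0.3):0.0,d:0.15);")
        rng = np.random.default_rng(5)
        seqs = {n: "".join(rng.choice(list("ACGT"), 40)) for n in "abcd"}
        aln = ElementAlignment("x", seqs)
        lls = [prune_loglik(t, aln, gtr) for t in (t1, t2, t3)]
        assert np.allclose(lls, lls[0], atol=1e-8)

    def test_tip_order_invariance(self, gtr):
        t1 = Phylogeny.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1);")
        t2 = Phylogeny.from_newick("((d:0.15,c:0.3):0.1,(b:0.2,a:0.1):0.05);")
        rng = np.random.default_rng(6)
        seqs = {n: "".join(rng.choice(list("ACGT"), 25)) for n in "abcd"}
        aln = ElementAlignment("x", seqs)
        assert np.isclose(prune_loglik(t1, aln, gtr),
                          prune_loglik(t2, aln, gtr), atol=1e-8)

    def test_unknown_taxon_rejected(self, gtr):
        tree = Phylogeny.from_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        aln = ElementAlignment("x", {"a": "A", "zzz": "A"})
        with pytest.raises(AlignmentTreeMismatchError):
            prune_loglik(tree, aln, gtr)


class TestFourfoldSites:
    def test_glycine_family_retained(self):
        aln = ElementAlignment("g", {"a": "GGA", "b": "GGC", "c": "GGG"})
        out = extract_4d_sites([aln])
        assert out.seqs == {"a": "A", "b": "C", "c": "G"}

    def test_non_fourfold_family_excluded(self):
        aln = ElementAlignment("g", {"a": "ATAGGA", "b": "ATGGGC"})
        out = extract_4d_sites([aln])
        assert out.length == 1          # only the GGN codon qualifies

    def test_prefix_disagreement_excluded(self):
        # both CTN (Leu) and GTN (Val) are fourfold, but prefixes differ
        aln = ElementAlignment("g", {"a": "CTAGGG", "b": "GTAGGC"})
        out = extract_4d_sites([aln])
        assert out.length == 1

    def test_gapped_codon_excluded(self):
        aln = ElementAlignment("g", {"a": "GG-GGA", "b": "GGAGGC"})
        assert extract_4d_sites([aln]).length == 1

    def test_frame_error(self):
        with pytest.raises(FrameError):
            extract_4d_sites([ElementAlignment("g", {"a": "GGAA", "b": "GGAC"})])


class TestNeutralFit:
    def test_simulation_recovery(self, owl_tree, neutral):
        aln = simulate_alignment(owl_tree, neutral,
                                 RegimeSpec.neutral(length=20_000, count=1),
                                 seed=11)[0]
        fit = fit_neutral_model(aln, owl_tree)
        assert np.all(np.abs(fit.pi - neutral.pi) < 0.02)
        truth_len = owl_tree.total_length
        assert abs(fit.tree.total_length - truth_len) / truth_len < 0.10
        # ML fit must beat the true simulation parameters
        ll_truth = prune_loglik(owl_tree, aln, neutral.gtr)
        assert fit.loglik >= ll_truth - 1e-6

    def test_insufficient_data(self, owl_tree):
        aln = ElementAlignment("x", {n: "NNNN" for n in owl_tree.tip_names})
        with pytest.raises(DataError):
            fit_neutral_model(aln, owl_tree)
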