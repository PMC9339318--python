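"""Substitution models, pruning likelihoods, and neutral-model fitting.

This is the numeric substrate of the whole analysis: a time-reversible GTR
model normalized to one expected substitution per unit branch length,
Felsenstein pruning over compressed site patterns (with per-pattern scaling
against underflow), fourfold-degenerate third-position extraction, and a
maximum-likelihood fit of the neutral model on 4d sites against which all
conservation and acceleration is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from Bio.Data import CodonTable

from .alignments import ElementAlignment, PatternData, encode_patterns, MISSING
from .errors import DataError, FrameError, InvalidParameterError
from .trees import Phylogeny

__all__ = [
    "GTRModel", "NeutralModel", "build_rate_matrix", "transition_matrix",
    "prune_loglik", "pattern_logliks", "extract_4d_sites", "fit_neutral_model",
    "FOURFOLD_PREFIXES",
]

# Exchangeability order over unordered base pairs, bases ordered A,C,G,T.
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT


def build_rate_matrix(exchangeabilities, frequencies) -> np.ndarray:
    """Reversible GTR generator normalized to unit expected rate.

    Q[i, j] = s_ij * pi_j for i != j; rows sum to zero; the stationary flow
    satisfies pi_i q_ij = pi_j q_ji by construction.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if s.shape != (6,) or not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise InvalidParameterError("need 6 finite positive exchangeabilities")
    if pi.shape != (4,) or not np.all(np.isfinite(pi)) or np.any(pi <= 0):
        raise InvalidParameterError("need 4 finite positive base frequencies")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(f"frequencies sum to {pi.sum():.12f}, not 1")
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, EXCH_PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    return Q / mean_rate


@dataclass
class GTRModel:
    """GTR model with a cached symmetric eigendecomposition.

    ``P(t) = exp(Qt)`` is evaluated as ``L diag(e^{lam t}) R`` where
    ``A = D^{1/2} Q D^{-1/2}`` is symmetric (D = diag(pi)), so batched
    transition matrices over many branch lengths are cheap.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.Q = build_rate_matrix(self.exchangeabilities, self.frequencies)
        sq = np.sqrt(self.frequencies)
        A = (self.Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((A + A.T) / 2.0)
        self._lam = lam
        self._left = V / sq[:, None]
        self._right = V.T * sq[None, :]

    @property
    def pi(self) -> np.ndarray:
        return self.frequencies

    def transition(self, t: float) -> np.ndarray:
        return self.transitions(np.array([float(t)]))[0]

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths (shape (*, 4, 4))."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise InvalidParameterError("branch length * multiplier must be >= 0")
        E = np.exp(np.multiply.outer(ts, self._lam))
        P = np.einsum("ij,...j,jk->...ik", self._left, E, self._right)
        np.clip(P, 0.0, 1.0, out=P)
        return P

    @classmethod
    def jukes_cantor(cls) -> "GTRModel":
        return cls(np.ones(6), np.full(4, 0.25))


def transition_matrix(model, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a GTRModel or a raw generator matrix."""
    if t < 0:
        raise InvalidParameterError(f"negative branch length {t}")
    if isinstance(model, GTRModel):
        return model.transition(t)
    Q = np.asarray(model, dtype=float)
    return expm(Q * t)


# -- pruning -------------------------------------------------------------


def pattern_logliks(tree: Phylogeny, patterns: PatternData, P: np.ndarray,
                    pi: np.ndarray) -> np.ndarray:
    """Per-pattern log-likelihood by pruning with per-pattern scaling.

    Parameters
    ----------
    P:
        Transition matrices per node, shape (n_nodes, S, S); the root's
        entry is ignored. ``S`` may be 4 (nucleotide) or 61 (codon).
    """
    n_states = pi.size
    n_pat = patterns.codes.shape[1]
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}

    def tip_partial(node: int) -> np.ndarray:
        codes = patterns.codes[node]
        out = np.zeros((n_pat, n_states))
        obs = codes < n_states
        out[np.arange(n_pat)[obs], codes[obs].astype(int)] = 1.0
        out[~obs] = 1.0
        return out

    for node in tree.postorder:
        kids = tree.children(node)
        if not kids:
            partial[node] = tip_partial(int(node))
            logscale[node] = np.zeros(n_pat)
            continue
        acc = np.ones((n_pat, n_states))
        scale = np.zeros(n_pat)
        for k in kids:
            acc *= partial.pop(k) @ P[k].T
            scale += logscale.pop(k)
        m = acc.max(axis=1)
        m[m == 0] = 1.0
        partial[node] = acc / m[:, None]
        logscale[node] = scale + np.log(m)
    root = tree.root
    site = partial[root] @ pi
    return np.log(site) + logscale[root]


def _node_transition_matrices(tree: Phylogeny, model: GTRModel,
                              multipliers=None) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    if multipliers is not None:
        if isinstance(multipliers, dict):
            for node, m in multipliers.items():
                mult[int(node)] = m
        else:
            mult = np.asarray(multipliers, dtype=float)
    if np.any(mult <= 0):
        raise InvalidParameterError("branch multipliers must be positive")
    return model.transitions(tree.lengths * mult)


def prune_loglik(tree: Phylogeny, aln: ElementAlignment, model: GTRModel,
                 branch_multipliers=None) -> float:
    """Total log-likelihood of the alignment under the scaled model.

    ``N`` and ``-`` columns marginalize as all-ones partials; an
    all-missing column therefore contributes exactly 0.
    """
    patterns = encode_patterns(aln, tree)
    P = _node_transition_matrices(tree, model, branch_multipliers)
    ll = pattern_logliks(tree, patterns, P, model.pi)
    return float(ll @ patterns.counts)


# -- fourfold-degenerate sites -------------------------------------------


def _fourfold_prefixes() -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    prefixes = set()
    for a in "ACGT":
        for b in "ACGT":
            codons = [a + b + c for c in "ACGT"]
            if any(c in table.stop_codons for c in codons):
                continue
            if len({table.forward_table[c] for c in codons}) == 1:
                prefixes.add(a + b)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def extract_4d_sites(codon_alignments: list[ElementAlignment],
                     element_id: str = "4d_sites") -> ElementAlignment:
    """Concatenated third positions of fourfold-degenerate codon columns.

    A codon column qualifies only when, in every taxon, the codon is
    ungapped and unambiguous, the first two positions are identical across
    all taxa, and that shared prefix defines a fourfold family. This is the
    strict cross-species reading used by PHAST-style 4d extraction.
    """
    if not codon_alignments:
        raise DataError("no codon alignments supplied")
    taxa = list(codon_alignments[0].taxa)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    for aln in codon_alignments:
        if aln.length % 3 != 0:
            raise FrameError(f"{aln.id}: length {aln.length} not a multiple of 3")
        if set(aln.taxa) != set(taxa):
            raise DataError(f"{aln.id}: inconsistent taxon set")
        for c in range(aln.length // 3):
            codons = {t: aln.seqs[t][3 * c: 3 * c + 3] for t in taxa}
            if any(set(cod) - set("ACGT") for cod in codons.values()):
                continue
            prefixes = {cod[:2] for cod in codons.values()}
            if len(prefixes) != 1 or next(iter(prefixes)) not in FOURFOLD_PREFIXES:
                continue
            for t in taxa:
                pieces[t].append(codons[t][2])
    if not pieces[taxa[0]]:
        raise DataError("no fourfold-degenerate sites found")
    return ElementAlignment(element_id, {t: "".join(p) for t, p in pieces.items()})


# -- neutral-model fit ---------------------------------------------------


@dataclass
class NeutralModel:
    """Fitted neutral reference: GTR parameters plus scaled tree.

    Branch lengths of ``tree`` are in neutral substitutions per site; all
    conservation (rho, r1) and acceleration (r2, subscale) downstream are
    multipliers of these lengths.
    """

    gtr: GTRModel
    tree: Phylogeny
    loglik: float = np.nan

    @property
    def pi(self) -> np.ndarray:
        return self.gtr.pi

    @property
    def Q(self) -> np.ndarray:
        return self.gtr.Q

    def to_dict(self) -> dict:
        return {
            "exchangeabilities": self.gtr.exchangeabilities.tolist(),
            "frequencies": self.gtr.pi.tolist(),
            "tree": self.tree.to_newick(),
            "foreground": self.tree.foreground_names,
            "outgroup": self.tree.outgroup,
            "loglik": float(self.loglik),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeutralModel":
        tree = Phylogeny.from_newick(d["tree"], foreground=d.get("foreground", ()),
                                     outgroup=d.get("outgroup"))
        return cls(GTRModel(np.array(d["exchangeabilities"]),
                            np.array(d["frequencies"])),
                   tree, d.get("loglik", np.nan))


def _empirical_frequencies(patterns: PatternData, tree: Phylogeny) -> np.ndarray:
    counts = np.zeros(4)
    for i in tree.tips:
        codes = patterns.codes[int(i)]
        for s in range(4):
            counts[s] += patterns.counts[codes == s].sum()
    if counts.sum() == 0:
        raise DataError("alignment contains no unambiguous bases")
    return (counts + 0.5) / (counts.sum() + 2.0)


def fit_neutral_model(fourfold_aln: ElementAlignment, topology: Phylogeny,
                      n_starts: int = 2, tol: float = 1e-8) -> NeutralModel:
    """ML fit of GTR exchangeabilities, frequencies and branch lengths.

    The topology is fixed; optimization runs bounded L-BFGS-B on
    log-transformed rates and branch lengths plus additive-log-ratio
    frequencies, from fixed starting points for reproducibility.
    """
    patterns = encode_patterns(fourfold_aln, topology)
    informative = (patterns.codes[topology.tips.astype(int)] != MISSING).any(axis=0)
    if not (patterns.counts[informative] > 0).any():
        raise DataError("no informative columns in 4d alignment")
    branches = topology.branches
    n_br = branches.size
    pi0 = _empirical_frequencies(patterns, topology)
    bl0 = np.where(topology.lengths[branches] > 0,
                   topology.lengths[branches], 0.1)

    def unpack(x):
        exch = np.append(np.exp(x[:5]), 1.0)
        alr = x[5:8]
        pi = np.append(np.exp(alr), 1.0)
        pi = pi / pi.sum()
        bl = np.exp(x[8:])
        return exch, pi, bl

    def nll(x):
        exch, pi, bl = unpack(x)
        try:
            model = GTRModel(exch, pi)
        except InvalidParameterError:
            return 1e12
        lengths = np.zeros(topology.n_nodes)
        lengths[branches] = bl
        P = model.transitions(lengths)
        ll = pattern_logliks(topology, patterns, P, model.pi)
        val = -(ll @ patterns.counts)
        return val if np.isfinite(val) else 1e12

    starts = []
    base_alr = np.log(pi0[:3] / pi0[3])
    starts.append(np.concatenate([np.zeros(5), base_alr, np.log(bl0)]))
    if n_starts > 1:
        exch_ts = np.log(np.array([1.0, 4.0, 1.0, 1.0, 4.0]))  # transition bias
        starts.append(np.concatenate([exch_ts, base_alr, np.log(bl0)]))
    bounds = ([(-7, 7)] * 5 + [(-7, 7)] * 3 + [(np.log(1e-6), np.log(10))] * n_br)
    best = None
    for x0 in starts[:n_starts]:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 1000, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    exch, pi, bl = unpack(best.x)
    lengths = np.zeros(topology.n_nodes)
    lengths[branches] = bl
    fitted = topology.with_lengths(lengths)
    return NeutralModel(GTRModel(exch, pi), fitted, loglik=-float(best.fun))
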