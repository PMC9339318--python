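"""Codon-model tests for accelerated protein evolution on foreground branches.

Implements a Goldman–Yang style codon substitution model (universal code,
61 sense codons, F3x4 frequencies), the branch model (one foreground
omega on the diurnal tip branches vs one background omega), the standard
branch-site Model A (site classes 0, 1, 2a, 2b; null fixes omega2 = 1),
and a per-foreground-branch two-ratio test with Holm–Bonferroni control
that plays the decision role of an adaptive branch-site screen: a gene is
"foreground specific" when at least two diurnal branches are individually
significant and no background branch is flagged by the same test.

Likelihoods are computed by pruning over compressed codon site patterns.
Under the reversible model the likelihood is root-placement invariant, so
the rooted topology can stand in for the unrooted tree used in practice.
The tree-scale factor and kappa are estimated once per gene under a
single-omega model and shared by the null and alternative fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from Bio.Data import CodonTable

from .alignments import PatternData
from .errors import DataError, FrameError, InvalidParameterError
from .phylo import pattern_logliks
from .trees import Phylogeny

__all__ = [
    "SENSE_CODONS", "CodonAlignment", "CodonModel", "SelectionTestResult",
    "build_codon_matrix", "f3x4_frequencies", "fit_branch_model",
    "fit_branch_site_model", "per_branch_foreground_test",
    "multiple_test_correct", "apply_fdr", "codon_loglik",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: list[str] = [
    "".join(c) for c in product("TCAG", repeat=3)
    if "".join(c) not in _TABLE.stop_codons
]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA = np.array([_TABLE.forward_table[c] for c in SENSE_CODONS])
_MISSING = len(SENSE_CODONS)  # 61
_PURINES = {"A", "G"}


def _pair_structure():
    """Single-nucleotide codon pairs with transition/synonymy flags."""
    ii, jj, ts, syn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append((ci[k] in _PURINES) == (cj[k] in _PURINES))
            syn.append(_AA[i] == _AA[j])
            pos.append(k)
    return (np.array(ii), np.array(jj), np.array(ts), np.array(syn),
            np.array(pos))


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN, _PAIR_POS = _pair_structure()


def build_codon_matrix(kappa: float, omega: float, codon_freqs) -> np.ndarray:
    """61x61 reversible codon generator, unit expected substitution rate.

    Rate i->j is zero for multi-nucleotide changes, and otherwise
    pi_j * kappa^[transition] * omega^[nonsynonymous].
    """
    if not (np.isfinite(kappa) and kappa > 0):
        raise InvalidParameterError(f"kappa must be positive, got {kappa}")
    if not (np.isfinite(omega) and omega >= 0):
        raise InvalidParameterError(f"omega must be non-negative, got {omega}")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (61,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
        raise InvalidParameterError("codon frequencies must be a 61-simplex")
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) \
        * np.where(_PAIR_SYN, 1.0, omega)
    Q = np.zeros((61, 61))
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise InvalidParameterError("degenerate codon model (zero expected rate)")
    return Q / mean_rate


def _raw_codon_rates(kappa, omega, pi):
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) \
        * np.where(_PAIR_SYN, 1.0, omega)
    Q = np.zeros((61, 61))
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class CodonModel:
    """Codon model with cached symmetric eigendecomposition for fast P(t).

    The generator is scaled by the expected rate of the *neutral* (omega=1)
    matrix with the same kappa and frequencies, so that site classes and
    branch classes within one model share a common time scale: omega > 1
    means genuinely faster evolution, not just a different substitution
    composition. (For a single-class model this differs from per-matrix
    unit normalization only by a constant absorbed into the tree scale.)
    """

    def __init__(self, kappa: float, omega: float, codon_freqs):
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.pi = np.asarray(codon_freqs, dtype=float)
        if not (np.isfinite(kappa) and kappa > 0):
            raise InvalidParameterError(f"kappa must be positive, got {kappa}")
        if not (np.isfinite(omega) and omega >= 0):
            raise InvalidParameterError(f"omega must be >= 0, got {omega}")
        Q = _raw_codon_rates(kappa, omega, self.pi)
        Q_neutral = _raw_codon_rates(kappa, 1.0, self.pi)
        divisor = -(self.pi * np.diag(Q_neutral)).sum()
        self.Q = Q / divisor
        sq = np.sqrt(np.maximum(self.pi, 1e-300))
        A = (self.Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((A + A.T) / 2.0)
        self._lam = lam
        self._left = V / sq[:, None]
        self._right = V.T * sq[None, :]

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        E = np.exp(np.multiply.outer(ts, self._lam))
        P = np.einsum("ij,...j,jk->...ik", self._left, E, self._right)
        np.clip(P, 0.0, None, out=P)
        return P

    def transition(self, t: float) -> np.ndarray:
        return self.transitions(np.array([float(t)]))[0]


@dataclass
class CodonAlignment:
    """In-frame codon alignment of one gene.

    Stop codons and frame-breaking codons (gaps or ambiguity inside the
    triplet) are masked to missing data at encoding time.
    """

    id: str
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        self.seqs = {t: s.upper() for t, s in self.seqs.items()}
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise DataError(f"{self.id}: unequal sequence lengths")
        if self.length % 3 != 0:
            raise FrameError(f"{self.id}: length {self.length} not in frame")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific base compositions (F3x4)."""
    counts = np.full((3, 4), 0.5)  # +1/2 smoothing keeps all freqs positive
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for seq in aln.seqs.values():
        for c in range(len(seq) // 3):
            cod = seq[3 * c: 3 * c + 3]
            if set(cod) - set("ACGT"):
                continue
            for k in range(3):
                counts[k, base_idx[cod[k]]] += 1
    pos = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array([pos[0, base_idx[c[0]]] * pos[1, base_idx[c[1]]]
                      * pos[2, base_idx[c[2]]] for c in SENSE_CODONS])
    return freqs / freqs.sum()


def encode_codon_patterns(aln: CodonAlignment, tree: Phylogeny) -> PatternData:
    missing_taxa = set(aln.taxa) - set(tree.tip_names)
    if missing_taxa:
        raise DataError(f"{aln.id}: taxa absent from tree: {sorted(missing_taxa)}")
    if len(set(aln.taxa) & set(tree.tip_names)) < 2:
        raise DataError(f"{aln.id}: fewer than two taxa shared with the tree")
    n_cod = aln.n_codons
    cols = np.full((tree.n_nodes, n_cod), _MISSING, dtype=np.int16)
    any_observed = np.zeros(n_cod, dtype=bool)
    for name, seq in aln.seqs.items():
        row = np.full(n_cod, _MISSING, dtype=np.int16)
        for c in range(n_cod):
            row[c] = CODON_INDEX.get(seq[3 * c: 3 * c + 3], _MISSING)
        cols[tree.tip_index(name)] = row
        any_observed |= row != _MISSING
    if not any_observed.any():
        raise DataError(f"{aln.id}: alignment is entirely missing data")
    uniq, inverse, counts = np.unique(cols.T, axis=0, return_inverse=True,
                                      return_counts=True)
    return PatternData(codes=uniq.T, counts=counts.astype(float),
                       pattern_of_column=inverse.astype(np.int64))


# -- likelihood evaluation ----------------------------------------------


class _CodonLikEngine:
    """Batched codon pruning over site classes for one gene.

    Tip partial-likelihood tables are built once; each call prunes all
    mixture classes in a single class-stacked pass with per-pattern
    scaling. P matrices are cached per (kappa, omega, scale), which makes
    the fixed-nuisance null/alt fits cheap.
    """

    def __init__(self, tree: Phylogeny, patterns: PatternData, freqs):
        self.tree = tree
        self.patterns = patterns
        self.freqs = np.asarray(freqs, dtype=float)
        self.n_pat = patterns.codes.shape[1]
        self._tip_partials: dict[int, np.ndarray] = {}
        for node in range(tree.n_nodes):
            if tree.children(node):
                continue
            codes = patterns.codes[node]
            part = np.zeros((self.n_pat, 61))
            obs = codes < 61
            part[np.arange(self.n_pat)[obs], codes[obs].astype(int)] = 1.0
            part[~obs] = 1.0
            self._tip_partials[node] = part
        self._postorder = tree.postorder
        self._model_cache: dict = {}
        self._P_cache: dict = {}

    def model(self, kappa: float, omega: float) -> CodonModel:
        key = (round(float(kappa), 12), round(float(omega), 12))
        m = self._model_cache.get(key)
        if m is None:
            m = CodonModel(kappa, omega, self.freqs)
            if len(self._model_cache) > 256:
                self._model_cache.clear()
            self._model_cache[key] = m
        return m

    def P_all_nodes(self, kappa: float, omega: float, scale: float) -> np.ndarray:
        key = (round(float(kappa), 12), round(float(omega), 12),
               round(float(scale), 12))
        P = self._P_cache.get(key)
        if P is None:
            P = self.model(kappa, omega).transitions(self.tree.lengths * scale)
            if len(self._P_cache) > 64:
                self._P_cache.clear()
            self._P_cache[key] = P
        return P

    def class_P(self, kappa: float, scale: float, class_pairs, foreground
                ) -> np.ndarray:
        """(C, n_nodes, 61, 61) stack for (omega_bg, omega_fg) pairs."""
        fg = sorted(foreground)
        stack = np.empty((len(class_pairs), self.tree.n_nodes, 61, 61))
        for c, (w_bg, w_fg) in enumerate(class_pairs):
            stack[c] = self.P_all_nodes(kappa, w_bg, scale)
            if fg and w_fg != w_bg:
                stack[c, fg] = self.P_all_nodes(kappa, w_fg, scale)[fg]
        return stack

    def pattern_logliks(self, P: np.ndarray) -> np.ndarray:
        """(C, n_pat) per-class per-pattern log-likelihoods."""
        C = P.shape[0]
        partial: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in self._postorder:
            node = int(node)
            kids = self.tree.children(node)
            if not kids:
                partial[node] = np.broadcast_to(
                    self._tip_partials[node], (C, self.n_pat, 61))
                logscale[node] = np.zeros((C, self.n_pat))
                continue
            acc = None
            scale = np.zeros((C, self.n_pat))
            for k in kids:
                lifted = np.matmul(partial.pop(k), P[:, k].transpose(0, 2, 1))
                acc = lifted if acc is None else acc * lifted
                scale += logscale.pop(k)
            m = acc.max(axis=2)
            m[m == 0] = 1.0
            partial[node] = acc / m[..., None]
            logscale[node] = scale + np.log(m)
        root = self.tree.root
        site = partial[root] @ self.freqs
        return np.log(site) + logscale[root]

    def loglik(self, kappa, scale, class_pairs, class_props, foreground) -> float:
        P = self.class_P(kappa, scale, class_pairs, foreground)
        ll = self.pattern_logliks(P)
        if len(class_pairs) == 1:
            total = ll[0]
        else:
            logw = np.log(np.maximum(np.asarray(class_props, dtype=float),
                                     1e-300))[:, None]
            total = logsumexp(ll + logw, axis=0)
        val = float(total @ self.patterns.counts)
        return val if np.isfinite(val) else -1e12


def codon_loglik(aln: CodonAlignment, tree: Phylogeny, kappa: float,
                 omega_bg: float, omega_fg: float | None = None,
                 scale: float = 1.0, freqs=None, foreground=None) -> float:
    """Codon pruning log-likelihood (reference entry point, uncached)."""
    patterns = encode_codon_patterns(aln, tree)
    freqs = f3x4_frequencies(aln) if freqs is None else np.asarray(freqs)
    foreground = tree.foreground if foreground is None else frozenset(foreground)
    omega_fg = omega_bg if omega_fg is None else omega_fg
    engine = _CodonLikEngine(tree, patterns, freqs)
    return engine.loglik(kappa, scale, [(omega_bg, omega_fg)], [1.0], foreground)


# -- results -------------------------------------------------------------


@dataclass
class SelectionTestResult:
    gene: str
    test: str
    lnL_null: float
    lnL_alt: float
    omega_background: float
    omega_foreground: float
    lrt: float
    df: int
    p: float
    kappa: float = np.nan
    p_adj: float | None = None
    accelerated: bool | None = None
    branch: str | None = None
    foreground_specific: bool | None = None
    params: dict = field(default_factory=dict)


def _lrt_p(lnL_null, lnL_alt, df, boundary=False):
    lrt = max(0.0, 2.0 * (lnL_alt - lnL_null))
    if boundary:
        # null parameter on the boundary: 50:50 mixture of chi2_0 and chi2_1
        p = 1.0 if lrt <= 0 else 0.5 * float(chi2.sf(lrt, 1))
    else:
        p = float(chi2.sf(lrt, df)) if lrt > 0 else 1.0
    return lrt, min(p, 1.0)


# -- branch model --------------------------------------------------------


def _fit_single_omega(engine: _CodonLikEngine):
    """Shared nuisance fit: kappa, tree scale, one omega."""

    def nll(x):
        kappa, scale, omega = np.exp(x)
        try:
            return -engine.loglik(kappa, scale, [(omega, omega)], [1.0],
                                  frozenset())
        except (InvalidParameterError, FloatingPointError):
            return 1e12

    x0 = np.log([2.0, 1.0, 0.3])
    bounds = [(np.log(0.05), np.log(50)), (np.log(1e-3), np.log(100)),
              (np.log(1e-4), np.log(20))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300, "ftol": 1e-10})
    kappa, scale, omega = np.exp(res.x)
    return kappa, scale, omega, -float(res.fun)


def fit_branch_model(aln: CodonAlignment, tree: Phylogeny,
                     foreground=None) -> SelectionTestResult:
    """Branch-model LRT: shared foreground omega vs single-omega null (df=1)."""
    foreground = tree.foreground if foreground is None else frozenset(foreground)
    if not foreground:
        raise InvalidParameterError("no foreground branches designated")
    engine = _CodonLikEngine(tree, encode_codon_patterns(aln, tree),
                             f3x4_frequencies(aln))
    kappa, scale, omega0, lnL0 = _fit_single_omega(engine)

    def nll_alt(x):
        w_bg, w_fg = np.exp(x)
        try:
            return -engine.loglik(kappa, scale, [(w_bg, w_fg)], [1.0],
                                  foreground)
        except (InvalidParameterError, FloatingPointError):
            return 1e12

    bounds = [(np.log(1e-4), np.log(20))] * 2
    res = minimize(nll_alt, np.log([omega0, omega0]), method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 300, "ftol": 1e-10})
    w_bg, w_fg = np.exp(res.x)
    lnL1 = max(-float(res.fun), lnL0)  # nested models: alt >= null
    lrt, p = _lrt_p(lnL0, lnL1, df=1)
    return SelectionTestResult(
        gene=aln.id, test="branch", lnL_null=lnL0, lnL_alt=lnL1,
        omega_background=float(w_bg), omega_foreground=float(w_fg),
        lrt=lrt, df=1, p=p, kappa=float(kappa),
        params={"scale": float(scale), "omega_null": float(omega0)})


# -- branch-site model (Model A) -----------------------------------------


def _model_a_props(q, f):
    """Class proportions (p0, p1, p2a, p2b) from q = p0+p1, f = p0/(p0+p1)."""
    p0, p1 = q * f, q * (1 - f)
    rest = 1 - q
    return np.array([p0, p1, rest * f, rest * (1 - f)])


def fit_branch_site_model(aln: CodonAlignment, tree: Phylogeny,
                          foreground=None,
                          omega2_starts=(1.5, 4.0, 16.0)) -> SelectionTestResult:
    """Branch-site Model A LRT; the null fixes omega2 = 1.

    Because the null pins omega2 on the boundary of the alternative's
    parameter space, p-values use the 0.5*chi2_0 + 0.5*chi2_1 mixture
    reference; df is reported as 1. The alternative is seeded from several
    fixed omega2 values (the best seed is optimized) to escape boundary
    local optima.
    """
    foreground = tree.foreground if foreground is None else frozenset(foreground)
    if not foreground:
        raise InvalidParameterError("no foreground branches designated")
    engine = _CodonLikEngine(tree, encode_codon_patterns(aln, tree),
                             f3x4_frequencies(aln))
    kappa, scale, _, _ = _fit_single_omega(engine)

    def nll(x, w2=None):
        q = 1 / (1 + np.exp(-x[0]))
        f = 1 / (1 + np.exp(-x[1]))
        w0 = np.exp(x[2])
        w2 = np.exp(x[3]) if w2 is None else w2
        pairs = [(w0, w0), (1.0, 1.0), (w0, w2), (1.0, w2)]
        try:
            return -engine.loglik(kappa, scale, pairs, _model_a_props(q, f),
                                  foreground)
        except (InvalidParameterError, FloatingPointError):
            return 1e12

    b_mix = [(-6, 6), (-6, 6), (np.log(1e-4), np.log(0.999))]
    x0 = np.array([1.5, 1.5, np.log(0.2)])
    res0 = minimize(lambda x: nll(x, w2=1.0), x0, method="L-BFGS-B",
                    bounds=b_mix, options={"maxiter": 200, "ftol": 1e-10})
    lnL0 = -float(res0.fun)

    seeds = [np.concatenate([res0.x, [np.log(w2)]]) for w2 in omega2_starts]
    seed_vals = [nll(x) for x in seeds]
    best_seed = seeds[int(np.argmin(seed_vals))]
    best = minimize(nll, best_seed, method="L-BFGS-B",
                    bounds=b_mix + [(0.0, np.log(50.0))],
                    options={"maxiter": 200, "ftol": 1e-10})
    lnL1 = max(-float(best.fun), lnL0)
    q = 1 / (1 + np.exp(-best.x[0]))
    f = 1 / (1 + np.exp(-best.x[1]))
    w0 = float(np.exp(best.x[2]))
    w2 = float(np.exp(best.x[3]))
    lrt, p = _lrt_p(lnL0, lnL1, df=1, boundary=True)
    return SelectionTestResult(
        gene=aln.id, test="branch_site", lnL_null=lnL0, lnL_alt=lnL1,
        omega_background=w0, omega_foreground=w2, lrt=lrt, df=1, p=p,
        kappa=float(kappa),
        params={"scale": float(scale), "proportions": _model_a_props(q, f).tolist(),
                "omega0": w0, "omega2": w2})


# -- per-branch two-ratio screen ----------------------------------------


def _two_ratio_for_branch(aln_id, tree, engine, branch, kappa, scale,
                          omega0, lnL0):
    target = frozenset([branch])

    def nll(x):
        w_bg, w_fg = np.exp(x)
        try:
            return -engine.loglik(kappa, scale, [(w_bg, w_fg)], [1.0], target)
        except (InvalidParameterError, FloatingPointError):
            return 1e12

    res = minimize(nll, np.log([omega0, omega0]), method="L-BFGS-B",
                   bounds=[(np.log(1e-4), np.log(50))] * 2,
                   options={"maxiter": 200, "ftol": 1e-10})
    w_bg, w_fg = np.exp(res.x)
    lnL1 = max(-float(res.fun), lnL0)
    lrt, p = _lrt_p(lnL0, lnL1, df=1)
    return SelectionTestResult(
        gene=aln_id, test="per_branch", lnL_null=lnL0, lnL_alt=lnL1,
        omega_background=float(w_bg), omega_foreground=float(w_fg),
        lrt=lrt, df=1, p=p, kappa=float(kappa),
        branch=tree.names[branch] or f"node{branch}")


def per_branch_foreground_test(alignments, tree: Phylogeny, candidate_genes,
                               alpha: float = 0.05) -> list[SelectionTestResult]:
    """Two-ratio LRT per foreground branch with Holm control per gene.

    For each candidate gene, every diurnal tip branch is tested on its own
    (that branch vs the rest); Holm–Bonferroni corrects across the gene's
    foreground branches. The same test is applied to every background
    branch (Holm within that family): a gene is foreground specific when
    at least two diurnal branches are individually significant and no
    background branch is flagged.
    """
    if isinstance(alignments, CodonAlignment):
        alignments = {alignments.id: alignments}
    elif not isinstance(alignments, dict):
        alignments = {a.id: a for a in alignments}
    results: list[SelectionTestResult] = []
    for gene in candidate_genes:
        aln = alignments[gene]
        engine = _CodonLikEngine(tree, encode_codon_patterns(aln, tree),
                                 f3x4_frequencies(aln))
        kappa, scale, omega0, lnL0 = _fit_single_omega(engine)
        fg = sorted(tree.foreground)
        bg = [int(b) for b in tree.branches if b not in tree.foreground]
        fg_rows = [_two_ratio_for_branch(aln.id, tree, engine, b,
                                         kappa, scale, omega0, lnL0)
                   for b in fg]
        bg_rows = [_two_ratio_for_branch(aln.id, tree, engine, b,
                                         kappa, scale, omega0, lnL0)
                   for b in bg]
        for rows in (fg_rows, bg_rows):
            if rows:
                adj = multiple_test_correct([r.p for r in rows], method="holm")
                for r, pa in zip(rows, adj):
                    r.p_adj = float(pa)
                    r.accelerated = bool(pa < alpha
                                         and r.omega_foreground > r.omega_background)
        n_fg_hits = sum(r.accelerated for r in fg_rows)
        bg_flagged = any(r.accelerated for r in bg_rows)
        specific = n_fg_hits >= 2 and not bg_flagged
        for r in fg_rows + bg_rows:
            r.foreground_specific = specific
        results.extend(fg_rows + bg_rows)
    return results


# -- multiple testing ----------------------------------------------------


def multiple_test_correct(pvalues, method: str = "BH") -> np.ndarray:
    """Adjusted p-values: Benjamini–Hochberg step-up or Holm step-down."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr": "fdr_bh", "holm": "holm"}.get(method.lower())
    if key is None:
        raise InvalidParameterError(f"unknown correction method {method!r}")
    return np.minimum(multipletests(p, method=key)[1], 1.0)


def apply_fdr(results: list[SelectionTestResult], alpha: float = 0.05,
              method: str = "BH") -> list[SelectionTestResult]:
    """Attach adjusted p-values; flag acceleration per the omega contrast."""
    if not results:
        return results
    adj = multiple_test_correct([r.p for r in results], method=method)
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        r.accelerated = bool(pa < alpha
                             and r.omega_foreground > r.omega_background)
    return results
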