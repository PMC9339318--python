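"""Bayesian conserved-to-accelerated rate-shift inference on elements.

Each element evolves under the neutral model with one latent state per
branch: neutral (rate r0 = 1), conserved (r1 < 1) or accelerated
(r2 > r1). States follow a Markov prior along the tree — the root is
neutral, a branch may switch neutral->conserved (probability alpha) or
conserved->accelerated (probability beta, only on branches allowed by the
model), and there are no reversals. Three nested models differ in where
acceleration is allowed: M0 nowhere, M1 only on the diurnal (foreground)
tip branches, M2 anywhere. Candidates for parallel diurnal acceleration
satisfy logBF1 = logML(M1) - logML(M0) >= 10, logBF2 = logML(M1) -
logML(M2) >= 1, and a posterior probability of acceleration above 0.8 in
at least two of the three diurnal species.

Rather than MCMC, the branch-state configuration shared by all columns of
an element is marginalized *exactly*: the no-reversal prior admits only a
few thousand configurations on the eight-tip tree, and a tree-shaped
dynamic program over subtree configurations (partial likelihood vectors
lifted through each branch once, then combined multiplicatively) evaluates
all of them simultaneously on a fixed quadrature grid over (r1, r2).

The module also houses the phyloP-style subscale LRT (one scale vs
separate foreground/background scales) used to compare coding and
noncoding acceleration magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from .alignments import ElementAlignment, PatternData, encode_patterns
from .codon import multiple_test_correct
from .errors import DataError, InvalidParameterError
from .phylo import NeutralModel, pattern_logliks
from .trees import Phylogeny

__all__ = [
    "RateShiftConfig", "RateShiftResult", "SubscaleResult",
    "latent_marginal_loglik", "fit_rate_shift", "call_candidate",
    "branch_state_prior", "fit_subscale_lrt", "add_subscale_fdr",
    "summarize_subscale_by_length",
]

NEUTRAL, CONSERVED, ACCELERATED = 0, 1, 2


# ======================================================================
# configuration
# ======================================================================


@dataclass(frozen=True)
class RateShiftConfig:
    """Latent-state prior and (r1, r2) quadrature for one nested model."""

    model: str                       # "M0" | "M1" | "M2"
    allowed: frozenset                # branches where conserved->accelerated
    # beta sets the M1-vs-M2 prior contrast: logBF2 for a cleanly
    # diurnal-accelerated element is bounded near n_background*log(1/(1-beta)),
    # so beta must be large enough for the logBF2 >= 1 calling rule to be
    # attainable at all (0.2 gives ~2.4 on this tree; 0.05 would cap it at ~0.6).
    alpha: float = 0.5
    beta: float = 0.2
    r1_bounds: tuple = (0.01, 1.0)
    r2_max: float = 4.0
    n_r1: int = 12
    n_r2: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise InvalidParameterError("alpha, beta must lie in (0, 1)")
        lo, hi = self.r1_bounds
        if not (0 < lo < hi <= 1.0):
            raise InvalidParameterError("r1 prior must lie inside (0, 1]")
        if self.r2_max <= hi:
            raise InvalidParameterError("r2 prior must exceed the r1 range")

    @classmethod
    def for_model(cls, tree: Phylogeny, model: str, **kw) -> "RateShiftConfig":
        """M0: acceleration nowhere; M1: diurnal tips; M2: any branch."""
        if model == "M0":
            allowed = frozenset()
        elif model == "M1":
            allowed = frozenset(tree.foreground)
        elif model == "M2":
            allowed = frozenset(int(b) for b in tree.branches)
        else:
            raise InvalidParameterError(f"unknown model {model!r}")
        return cls(model=model, allowed=allowed, **kw)

    @classmethod
    def triple(cls, tree: Phylogeny, **kw):
        return tuple(cls.for_model(tree, m, **kw) for m in ("M0", "M1", "M2"))


def branch_state_prior(cfg: RateShiftConfig, tree: Phylogeny) -> np.ndarray:
    """log transition matrix Phi_b[z_parent, z_child] per branch (node).

    From neutral: stay (1-alpha) or turn conserved (alpha). From
    conserved: stay, or accelerate with probability beta on allowed
    branches. Accelerated is absorbing (no reversals).
    """
    logphi = np.full((tree.n_nodes, 3, 3), -np.inf)
    for b in range(tree.n_nodes):
        logphi[b, 0, 0] = np.log1p(-cfg.alpha)
        logphi[b, 0, 1] = np.log(cfg.alpha)
        if b in cfg.allowed:
            logphi[b, 1, 1] = np.log1p(-cfg.beta)
            logphi[b, 1, 2] = np.log(cfg.beta)
        else:
            logphi[b, 1, 1] = 0.0
        logphi[b, 2, 2] = 0.0
    return logphi


# ======================================================================
# exact enumeration via a tree-shaped DP over subtree configurations
# ======================================================================

# Minimal parent states compatible with a child state, as bitmasks over
# {neutral, conserved, accelerated}: a child can be neutral only under a
# neutral parent, conserved under neutral/conserved, accelerated under
# conserved/accelerated.
_PARENT_MASK = {0: 0b001, 1: 0b011, 2: 0b110}


class _ConfigDP:
    """Topology-level bookkeeping of all admissible state configurations.

    For every node the DP records its *lifted* configurations (the state
    of the node's own branch plus one configuration of the subtree below)
    and, for internal nodes, the cross products of children lifted
    configurations that share a compatible parent state. Likelihood
    evaluation later replays this structure with numeric arrays.
    """

    def __init__(self, tree: Phylogeny, cfg: RateShiftConfig):
        self.tree = tree
        self.cfg = cfg
        logphi = branch_state_prior(cfg, tree)
        # states each node's branch can reach given the root is neutral
        reach: dict[int, set] = {tree.root: {0}}
        for node in tree.postorder[::-1]:
            node = int(node)
            if node == tree.root:
                continue
            par = reach[int(tree.parent[node])]
            states = set()
            if 0 in par:
                states |= {0, 1}
            if 1 in par:
                states |= {1}
                if node in cfg.allowed:
                    states |= {2}
            if 2 in par:
                states |= {2}
            reach[node] = states

        # per node: lift_z, lift_e, lift_lp (subtree prior given own state),
        # lift_mask (compatible parent states); internal: per child the
        # lifted index that each E entry references
        self.lift_z: dict[int, np.ndarray] = {}
        self.lift_e: dict[int, np.ndarray] = {}
        self.lift_lp: dict[int, np.ndarray] = {}
        self.lift_mask: dict[int, np.ndarray] = {}
        self.e_children: dict[int, list[np.ndarray]] = {}
        self.e_lp: dict[int, np.ndarray] = {}
        self.lift_Z: dict[int, np.ndarray] = {}   # branch states per lifted cfg
        self.branch_order: dict[int, list[int]] = {}

        for node in tree.postorder:
            node = int(node)
            kids = tree.children(node)
            if not kids:
                z = np.array(sorted(reach[node]), dtype=np.int8)
                self.lift_z[node] = z
                self.lift_e[node] = np.zeros(z.size, dtype=np.int64)
                self.lift_lp[node] = np.zeros(z.size)
                self.lift_mask[node] = np.array(
                    [_PARENT_MASK[int(s)] for s in z], dtype=np.int8)
                self.e_children[node] = []
                self.e_lp[node] = np.zeros(1)
                self.lift_Z[node] = z[:, None].copy()
                self.branch_order[node] = [node]
                continue
            # merge children cross products, keeping combos with a
            # non-empty intersection of compatible parent states
            idx = [np.arange(self.lift_z[kids[0]].size)]
            mask = self.lift_mask[kids[0]].copy()
            lp = self.lift_lp[kids[0]].copy()
            for k in kids[1:]:
                m2 = self.lift_mask[k]
                comb = mask[:, None] & m2[None, :]
                keep_a, keep_b = np.nonzero(comb)
                idx = [a[keep_a] for a in idx] + [keep_b]
                mask = comb[keep_a, keep_b]
                lp = lp[keep_a] + self.lift_lp[k][keep_b]
            self.e_children[node] = idx
            n_e = mask.size
            branch_list = ([] if node == tree.root else [node])
            for k in kids:
                branch_list.extend(self.branch_order[k])
            self.branch_order[node] = branch_list
            e_Z = np.concatenate(
                [self.lift_Z[k][idx[c]] for c, k in enumerate(kids)], axis=1)

            if node == tree.root:
                root_lp = lp.copy()
                keep = np.zeros(n_e, dtype=bool)
                for c, k in enumerate(kids):
                    zc = self.lift_z[k][idx[c]]
                    root_lp += logphi[k, 0, zc]
                keep = np.isfinite(root_lp)
                self.e_children[node] = [a[keep] for a in idx]
                self.e_lp[node] = root_lp[keep]
                self.lift_Z[node] = e_Z[keep]
                continue

            self.e_lp[node] = lp
            # lift through this node's own branch
            lz, le, llp, lmask, lZ = [], [], [], [], []
            own_states = sorted(reach[node])
            for z in own_states:
                trans = np.zeros(n_e)
                for c, k in enumerate(kids):
                    zc = self.lift_z[k][idx[c]]
                    trans = trans + logphi[k, z, zc]
                ok = np.isfinite(trans)
                if not ok.any():
                    continue
                e_idx = np.flatnonzero(ok)
                lz.append(np.full(e_idx.size, z, dtype=np.int8))
                le.append(e_idx)
                llp.append(lp[e_idx] + trans[e_idx])
                lmask.append(np.full(e_idx.size, _PARENT_MASK[z], dtype=np.int8))
                lZ.append(np.concatenate(
                    [np.full((e_idx.size, 1), z, dtype=np.int8), e_Z[e_idx]],
                    axis=1))
            self.lift_z[node] = np.concatenate(lz)
            self.lift_e[node] = np.concatenate(le)
            self.lift_lp[node] = np.concatenate(llp)
            self.lift_mask[node] = np.concatenate(lmask)
            self.lift_Z[node] = np.concatenate(lZ)

    @property
    def n_configs(self) -> int:
        return self.e_lp[self.tree.root].size

    def config_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(Z, log prior) over all admissible configurations.

        Z has one row per configuration and one column per node (the root
        column is fixed at neutral).
        """
        root = self.tree.root
        order = self.branch_order[root]
        Z = np.zeros((self.n_configs, self.tree.n_nodes), dtype=np.int8)
        Z[:, order] = self.lift_Z[root]
        return Z, self.e_lp[root].copy()


_DP_CACHE: dict = {}


def _config_dp(tree: Phylogeny, cfg: RateShiftConfig) -> _ConfigDP:
    key = (id(tree), cfg.model, cfg.allowed, round(cfg.alpha, 12),
           round(cfg.beta, 12))
    dp = _DP_CACHE.get(key)
    if dp is None:
        dp = _ConfigDP(tree, cfg)
        if len(_DP_CACHE) > 32:
            _DP_CACHE.clear()
        _DP_CACHE[key] = dp
    return dp


def _config_logliks(dp: _ConfigDP, patterns: PatternData, model: NeutralModel,
                    r_grid: np.ndarray, chunk: int = 3,
                    dtype=np.float64) -> np.ndarray:
    """Per-configuration, per-grid-point data log-likelihood.

    ``r_grid`` has shape (G, 2) with columns (r1, r2); returns (n_cfg, G).
    float32 partials are adequate for the quadrature scan (the Bayes
    factors are thresholded at whole log units); the single-point oracle
    path runs in float64.
    """
    tree = dp.tree
    pi = model.pi.astype(dtype)
    counts = patterns.counts
    n_pat = patterns.codes.shape[1]
    tip_part: dict[int, np.ndarray] = {}
    for node in range(tree.n_nodes):
        if tree.children(node):
            continue
        codes = patterns.codes[node]
        part = np.zeros((n_pat, 4), dtype=dtype)
        obs = codes < 4
        part[np.arange(n_pat)[obs], codes[obs].astype(int)] = 1.0
        part[~obs] = 1.0
        tip_part[node] = part

    G = r_grid.shape[0]
    out = np.empty((dp.n_configs, G))
    for g0 in range(0, G, chunk):
        sl = slice(g0, min(g0 + chunk, G))
        gc = sl.stop - sl.start
        rates = np.stack([np.ones(gc), r_grid[sl, 0], r_grid[sl, 1]])
        ts = tree.lengths[:, None, None] * rates[None]           # (n, 3, Gc)
        P = model.gtr.transitions(ts.reshape(-1)).reshape(
            tree.n_nodes, 3, gc, 4, 4).astype(dtype)
        PT = P.transpose(0, 1, 2, 4, 3).copy()
        # layout (Gc, E, p, 4): the per-branch lift is then one large
        # GEMM per grid point instead of many tiny batched products
        lifted: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            node = int(node)
            kids = tree.children(node)
            if not kids:
                D = np.broadcast_to(tip_part[node], (gc, 1, n_pat, 4))
            else:
                D = None
                for c, k in enumerate(kids):
                    U = lifted.pop(k)[:, dp.e_children[node][c]]
                    D = U if D is None else D * U
            if node == tree.root:
                site = (D @ pi).astype(np.float64)
                out[:, sl] = (np.log(site) @ counts).T
                break
            lz, le = dp.lift_z[node], dp.lift_e[node]
            U = np.empty((gc, lz.size, n_pat, 4), dtype=dtype)
            for z in np.unique(lz):
                rows = lz == z
                sub = np.ascontiguousarray(D[:, le[rows]])
                n_e = sub.shape[1]
                prod = np.matmul(sub.reshape(gc, n_e * n_pat, 4), PT[node, z])
                U[:, rows] = prod.reshape(gc, n_e, n_pat, 4)
            lifted[node] = U
    return out


# ======================================================================
# marginal likelihood, Bayes factors, posteriors
# ======================================================================


def _quadrature(cfg: RateShiftConfig):
    """Midpoint rule on log-spaced nodes under uniform (r1, r2) priors.

    r1 ~ Uniform(r1_bounds); r2 | r1 ~ Uniform(r1, r2_max]. Returns a
    flattened (G, 2) grid and log-weights summing to ~0 (proper prior).
    """
    lo, hi = cfg.r1_bounds
    edges1 = np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_r1 + 1))
    r1 = np.sqrt(edges1[:-1] * edges1[1:])
    w1 = np.diff(edges1) / (hi - lo)
    grid, logw = [], []
    for a, wa in zip(r1, w1):
        edges2 = np.exp(np.linspace(np.log(a), np.log(cfg.r2_max),
                                    cfg.n_r2 + 1))
        r2 = np.sqrt(edges2[:-1] * edges2[1:])
        w2 = np.diff(edges2) / (cfg.r2_max - a)
        for b, wb in zip(r2, w2):
            grid.append((a, b))
            logw.append(np.log(wa) + np.log(wb))
    return np.array(grid), np.array(logw)


def _quadrature_r1_only(cfg: RateShiftConfig):
    lo, hi = cfg.r1_bounds
    edges1 = np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_r1 + 1))
    r1 = np.sqrt(edges1[:-1] * edges1[1:])
    w1 = np.diff(edges1) / (hi - lo)
    grid = np.stack([r1, np.full(r1.size, cfg.r2_max)], axis=1)
    return grid, np.log(w1)


def latent_marginal_loglik(aln: ElementAlignment, model: NeutralModel,
                           cfg: RateShiftConfig, r1: float, r2: float,
                           tree: Phylogeny | None = None) -> float:
    """Exact log-likelihood marginal over admissible branch-state
    configurations at a single rate pair (r1, r2).

    Equals brute-force enumeration over all permitted configurations of
    prior(config) * pruning-likelihood(config) — the sum runs over one
    configuration shared by every column of the element.
    """
    if not (0 < r1 < 1 or (cfg.model == "M0" and 0 < r1 <= 1)):
        if not 0 < r1 <= 1:
            raise InvalidParameterError(f"r1 must lie in (0, 1), got {r1}")
    if r2 <= r1:
        raise InvalidParameterError(f"need r2 > r1, got r1={r1}, r2={r2}")
    tree = model.tree if tree is None else tree
    dp = _config_dp(tree, cfg)
    patterns = encode_patterns(aln, tree)
    ll = _config_logliks(dp, patterns, model, np.array([[r1, r2]]))[:, 0]
    _, lp = dp.config_matrix()
    return float(logsumexp(lp + ll))


@dataclass
class RateShiftResult:
    """Marginal likelihoods, Bayes factors and acceleration posteriors."""

    element: str
    logml: dict[str, float]
    logbf1: float
    logbf2: float
    pp_m2: dict[str, float]
    pp_m1: dict[str, float]
    r1_hat: float
    r2_hat: float
    candidate: bool = False
    length: int = 0
    element_class: str = "owl_cnee"
    extras: dict = field(default_factory=dict)

    def diurnal_pp(self, tree: Phylogeny, under: str = "M2") -> list[float]:
        pp = self.pp_m2 if under == "M2" else self.pp_m1
        return [pp[tree.names[b]] for b in sorted(tree.foreground)]


def _model_run(tree, patterns, model, cfg):
    dp = _config_dp(tree, cfg)
    if cfg.model == "M0":
        grid, logw = _quadrature_r1_only(cfg)
    else:
        grid, logw = _quadrature(cfg)
    ll = _config_logliks(dp, patterns, model, grid, dtype=np.float32)
    Z, lp = dp.config_matrix()
    joint = lp[:, None] + logw[None, :] + ll            # (n_cfg, G)
    logml = float(logsumexp(joint))
    post = np.exp(joint - logml)
    pp_accel = np.array([(post * (Z[:, [b]] == ACCELERATED)).sum()
                         for b in range(tree.n_nodes)])
    r1_hat = float((post.sum(axis=0) * grid[:, 0]).sum())
    r2_hat = float((post.sum(axis=0) * grid[:, 1]).sum())
    return logml, pp_accel, r1_hat, r2_hat


def fit_rate_shift(aln: ElementAlignment, model: NeutralModel,
                   cfgs=None, tree: Phylogeny | None = None,
                   min_length: int = 50,
                   bf1_min: float = 10.0, bf2_min: float = 1.0,
                   pp_min: float = 0.8, min_diurnal: int = 2,
                   element_class: str = "owl_cnee") -> RateShiftResult:
    """Fit M0/M1/M2, form Bayes factors, decode acceleration posteriors.

    The marginal likelihood of each model integrates the exact
    configuration sum over the (r1, r2) prior by fixed-grid quadrature;
    posteriors are mixture-weighted over the same grid. Point estimates
    r1_hat, r2_hat are posterior means under M1.
    """
    tree = model.tree if tree is None else tree
    if aln.length < min_length:
        raise DataError(f"{aln.id}: element shorter than {min_length} bp")
    if cfgs is None:
        cfgs = RateShiftConfig.triple(tree)
    by_model = {c.model: c for c in cfgs}
    patterns = encode_patterns(aln, tree)
    logml: dict[str, float] = {}
    pp = {}
    r_hats = {}
    for name in ("M0", "M1", "M2"):
        logml[name], pp[name], r1_hat, r2_hat = _model_run(
            tree, patterns, model, by_model[name])
        r_hats[name] = (r1_hat, r2_hat)
    names = [tree.names[b] or f"node{b}" for b in range(tree.n_nodes)]
    result = RateShiftResult(
        element=aln.id,
        logml=logml,
        logbf1=logml["M1"] - logml["M0"],
        logbf2=logml["M1"] - logml["M2"],
        pp_m2={names[b]: float(pp["M2"][b]) for b in range(tree.n_nodes)
               if b != tree.root},
        pp_m1={names[b]: float(pp["M1"][b]) for b in range(tree.n_nodes)
               if b != tree.root},
        r1_hat=r_hats["M1"][0], r2_hat=r_hats["M1"][1],
        length=aln.length, element_class=element_class)
    result.candidate = call_candidate(result, tree, bf1_min, bf2_min,
                                      pp_min, min_diurnal)
    return result


def score_branch_posteriors(aln: ElementAlignment, model: NeutralModel,
                            tree: Phylogeny | None = None,
                            n_r1: int = 4, n_r2: int = 4,
                            **cfg_kw) -> dict[str, float]:
    """Per-branch M2 acceleration posteriors on a coarse (r1, r2) grid.

    A cheap scoring mode for ranking large element sets: identical
    estimator to ``fit_rate_shift``'s M2 posteriors, only with fewer
    quadrature nodes (branch posteriors are insensitive to fine rate
    resolution).
    """
    tree = model.tree if tree is None else tree
    cfg = RateShiftConfig.for_model(tree, "M2", n_r1=n_r1, n_r2=n_r2,
                                    **cfg_kw)
    patterns = encode_patterns(aln, tree)
    _, pp, _, _ = _model_run(tree, patterns, model, cfg)
    return {tree.names[b] or f"node{b}": float(pp[b])
            for b in range(tree.n_nodes) if b != tree.root}


def call_candidate(result: RateShiftResult, tree: Phylogeny,
                   bf1_min: float = 10.0, bf2_min: float = 1.0,
                   pp_min: float = 0.8, min_diurnal: int = 2) -> bool:
    """The study's candidate rule for parallel diurnal acceleration:
    logBF1 >= 10, logBF2 >= 1, and M2 acceleration posterior > 0.8 on at
    least two of the three diurnal tip branches."""
    n_hot = sum(p > pp_min for p in result.diurnal_pp(tree, under="M2"))
    return bool(result.logbf1 >= bf1_min and result.logbf2 >= bf2_min
                and n_hot >= min_diurnal)


# ======================================================================
# phyloP-style subscale LRT
# ======================================================================


@dataclass
class SubscaleResult:
    """Lineage-specific scale LRT for one element."""

    element: str
    element_class: str               # gene | avian_cnee | owl_cnee
    length: int
    scale_null: float
    scale_fg: float
    scale_bg: float
    lnl_null: float
    lnl_alt: float
    lrt: float
    p: float
    q: float | None = None
    significant: bool | None = None

    @property
    def subscale(self) -> float:
        return self.scale_fg / self.scale_bg


def fit_subscale_lrt(aln: ElementAlignment, model: NeutralModel,
                     tree: Phylogeny | None = None,
                     element_class: str = "owl_cnee") -> SubscaleResult:
    """One shared scale (null) vs foreground/background scales (alt), df=1.

    Scales multiply the neutral branch lengths; the subscale statistic is
    the ratio foreground/background in the alternative. Both genes and
    noncoding elements enter as plain nucleotide alignments.
    """
    tree = model.tree if tree is None else tree
    patterns = encode_patterns(aln, tree)
    tip_codes = patterns.codes[[int(i) for i in tree.tips]]
    if not ((tip_codes < 4).any(axis=0) & (patterns.counts > 0)).any():
        raise DataError(f"{aln.id}: no observed bases")
    fg = np.zeros(tree.n_nodes, dtype=bool)
    fg[sorted(tree.foreground)] = True

    def loglik(scale_fg: float, scale_bg: float) -> float:
        mult = np.where(fg, scale_fg, scale_bg)
        P = model.gtr.transitions(tree.lengths * mult)
        return float(pattern_logliks(tree, patterns, P, model.pi)
                     @ patterns.counts)

    lo, hi = np.log(1e-3), np.log(100.0)
    res0 = minimize_scalar(lambda x: -loglik(np.exp(x), np.exp(x)),
                           bounds=(lo, hi), method="bounded",
                           options={"xatol": 1e-8})
    s0 = float(np.exp(res0.x))
    lnl0 = -float(res0.fun)
    res1 = minimize(lambda x: -loglik(np.exp(x[0]), np.exp(x[1])),
                    np.log([s0, s0]), method="L-BFGS-B",
                    bounds=[(lo, hi)] * 2,
                    options={"maxiter": 200, "ftol": 1e-12})
    s_fg, s_bg = np.exp(res1.x)
    lnl1 = max(-float(res1.fun), lnl0)
    lrt = max(0.0, 2.0 * (lnl1 - lnl0))
    p = float(chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    return SubscaleResult(
        element=aln.id, element_class=element_class, length=aln.length,
        scale_null=s0, scale_fg=float(s_fg), scale_bg=float(s_bg),
        lnl_null=lnl0, lnl_alt=lnl1, lrt=lrt, p=p)


def add_subscale_fdr(results: list[SubscaleResult], alpha: float = 0.05,
                     by_class: bool = True) -> list[SubscaleResult]:
    """BH correction within each element class; significance requires both
    subscale > 1 and FDR q < alpha (the study's genome-wide rule)."""
    groups: dict[str, list[SubscaleResult]] = {}
    for r in results:
        groups.setdefault(r.element_class if by_class else "all", []).append(r)
    for rows in groups.values():
        qs = multiple_test_correct([r.p for r in rows], method="BH")
        for r, q in zip(rows, qs):
            r.q = float(q)
            r.significant = bool(r.subscale > 1.0 and q < alpha)
    return results


DEFAULT_LENGTH_BINS = (0, 200, 400, 600, 800, 1000, np.inf)

# Length exclusions of the binned comparison: genes longer than 1,000 bp
# and avian-specific CNEEs shorter than 200 bp fall outside the range
# where all element classes have data.
LENGTH_EXCLUSIONS = {"gene": (0, 1000), "avian_cnee": (200, np.inf)}


def summarize_subscale_by_length(results: list[SubscaleResult],
                                 bins=DEFAULT_LENGTH_BINS,
                                 only_significant: bool = True,
                                 apply_exclusions: bool = True
                                 ) -> pd.DataFrame:
    """Median and quartiles of log10(subscale) per element class and
    length interval, mirroring the study's length-stratified comparison."""
    rows = []
    for r in results:
        if only_significant and not r.significant:
            continue
        if apply_exclusions:
            lo, hi = LENGTH_EXCLUSIONS.get(r.element_class, (0, np.inf))
            if not lo <= r.length <= hi:
                continue
        rows.append({"element_class": r.element_class, "length": r.length,
                     "log10_subscale": np.log10(r.subscale)})
    if not rows:
        return pd.DataFrame(columns=["element_class", "length_bin", "n",
                                     "median", "q1", "q3"])
    df = pd.DataFrame(rows)
    df["length_bin"] = pd.cut(df["length"], bins=list(bins), right=True)
    grouped = (df.groupby(["element_class", "length_bin"], observed=True)
               ["log10_subscale"]
               .agg(n="size", median="median",
                    q1=lambda s: s.quantile(0.25),
                    q3=lambda s: s.quantile(0.75))
               .reset_index())
    return grouped[grouped["n"] > 0].reset_index(drop=True)
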