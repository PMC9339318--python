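"""Conserved-element discovery with a two-state phylogenetic HMM.

A phastCons-style segmentation: each alignment column is emitted either by
the neutral model or by the same model with all branch lengths shrunk by a
factor rho in (0, 1]. A two-state Markov chain (conserved <-> neutral)
ties columns together; forward-backward posteriors are thresholded into
maximal conserved runs, and segments shorter than the study's minimum
length (50 bp) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignments import ElementAlignment, encode_patterns
from .errors import InvalidParameterError
from .phylo import NeutralModel, pattern_logliks
from .trees import Phylogeny

__all__ = ["ConservedSegment", "column_scaled_loglik",
           "decode_conserved_segments", "filter_min_length",
           "forward_total_loglik", "refine_rho", "subtract_intervals"]


@dataclass
class ConservedSegment:
    """A maximal run of columns called conserved (0-based, half-open)."""

    chrom: str | None
    start: int
    end: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidParameterError(
                f"segment {self.chrom}:{self.start}-{self.end} is empty")
        if not 0.0 <= self.mean_posterior <= 1.0:
            raise InvalidParameterError("posterior outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_bed6(self, name: str = ".") -> tuple:
        return (self.chrom or ".", self.start, self.end, name,
                int(round(self.mean_posterior * 1000)), "+")


def column_scaled_loglik(aln: ElementAlignment, model: NeutralModel,
                         rho: float, tree: Phylogeny | None = None
                         ) -> np.ndarray:
    """Per-column log-likelihood with every branch scaled by rho.

    All-missing columns contribute exactly 0, matching the pruning
    convention used everywhere else.
    """
    if not (np.isfinite(rho) and rho > 0):
        raise InvalidParameterError(f"rho must be positive, got {rho}")
    tree = model.tree if tree is None else tree
    patterns = encode_patterns(aln, tree)
    P = model.gtr.transitions(tree.lengths * rho)
    ll = pattern_logliks(tree, patterns, P, model.pi)
    return ll[patterns.pattern_of_column]


def _chain_logparams(mu: float, nu: float):
    if not (0 < mu < 1 and 0 < nu < 1):
        raise InvalidParameterError("switch probabilities must lie in (0, 1)")
    # stationary start: pi_cons = nu/(mu+nu)
    log_start = np.log(np.array([nu, mu]) / (mu + nu))
    log_trans = np.log(np.array([[1 - mu, mu], [nu, 1 - nu]]))
    return log_start, log_trans  # state 0 = conserved, 1 = neutral


def _log_emissions(aln, model, rho, tree):
    e_cons = column_scaled_loglik(aln, model, rho, tree)
    e_neut = column_scaled_loglik(aln, model, 1.0, tree)
    return np.stack([e_cons, e_neut], axis=1)


def forward_total_loglik(aln: ElementAlignment, model: NeutralModel,
                         rho: float, mu: float, nu: float,
                         tree: Phylogeny | None = None) -> float:
    """Total HMM log-likelihood (forward recursion, log space)."""
    log_start, log_trans = _chain_logparams(mu, nu)
    emis = _log_emissions(aln, model, rho, tree)
    f = log_start + emis[0]
    for c in range(1, emis.shape[0]):
        f = emis[c] + np.logaddexp(f[0] + log_trans[0], f[1] + log_trans[1])
    return float(np.logaddexp(f[0], f[1]))


def _posteriors(emis: np.ndarray, mu: float, nu: float) -> np.ndarray:
    """Forward-backward state posteriors, columns x {conserved, neutral}."""
    log_start, log_trans = _chain_logparams(mu, nu)
    n = emis.shape[0]
    fwd = np.empty((n, 2))
    fwd[0] = log_start + emis[0]
    for c in range(1, n):
        fwd[c] = emis[c] + np.logaddexp(fwd[c - 1, 0] + log_trans[0],
                                        fwd[c - 1, 1] + log_trans[1])
    bwd = np.empty((n, 2))
    bwd[-1] = 0.0
    for c in range(n - 2, -1, -1):
        tmp = log_trans + (emis[c + 1] + bwd[c + 1])[None, :]
        bwd[c] = np.logaddexp(tmp[:, 0], tmp[:, 1])
    post = fwd + bwd
    post -= np.logaddexp(post[:, 0], post[:, 1])[:, None]
    return np.exp(post)


def decode_conserved_segments(aln: ElementAlignment, model: NeutralModel,
                              rho: float = 0.3, mu: float = 1 / 45,
                              nu: float = 1 / 100,
                              posterior_cutoff: float = 0.5,
                              tree: Phylogeny | None = None
                              ) -> list[ConservedSegment]:
    """Posterior-decode maximal conserved runs of the two-state HMM.

    Coordinates of the returned segments are genomic when the alignment
    carries a coordinate record, else alignment-column offsets.
    """
    if not 0 < posterior_cutoff < 1:
        raise InvalidParameterError("posterior cutoff must lie in (0, 1)")
    emis = _log_emissions(aln, model, rho, tree)
    post = _posteriors(emis, mu, nu)
    conserved = post[:, 0] >= posterior_cutoff
    offset = aln.start or 0
    segments: list[ConservedSegment] = []
    c = 0
    n = conserved.size
    while c < n:
        if not conserved[c]:
            c += 1
            continue
        run_start = c
        while c < n and conserved[c]:
            c += 1
        segments.append(ConservedSegment(
            aln.chrom, offset + run_start, offset + c,
            float(post[run_start:c, 0].mean())))
    return segments


def filter_min_length(segments: list[ConservedSegment],
                      min_len: int = 50) -> list[ConservedSegment]:
    """Drop segments shorter than ``min_len`` (the study excludes <50 bp)."""
    return [s for s in segments if s.length >= min_len]


def refine_rho(aln: ElementAlignment, model: NeutralModel, mu: float = 1 / 45,
               nu: float = 1 / 100, bounds=(0.02, 0.99),
               tree: Phylogeny | None = None) -> float:
    """Bounded 1-D ML refinement of the conserved scale over one input."""
    res = minimize_scalar(
        lambda r: -forward_total_loglik(aln, model, r, mu, nu, tree),
        bounds=bounds, method="bounded", options={"xatol": 1e-3})
    return float(res.x)


def subtract_intervals(space: list[tuple[int, int]],
                       masks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Remove masked intervals (e.g. gene bodies) from a searchable space."""
    out = []
    for start, end in space:
        cuts = sorted((max(start, s), min(end, e)) for s, e in masks
                      if s < end and e > start)
        pos = start
        for s, e in cuts:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < end:
            out.append((pos, end))
    return out
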