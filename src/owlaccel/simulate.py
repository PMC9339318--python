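"""Synthetic data emulating the eight-taxon owl study design.

Everything the pipeline consumes can be generated here: the fixture
phylogeny (three diurnal foreground tips, cuckoo roller outgroup),
nucleotide elements evolving under neutral / conserved / diurnal-accelerated
regimes, in-frame codon alignments with foreground-background omega
contrasts, and a toy annotated chromosome with a planted GO enrichment
signal. All randomness flows through numpy SeedSequence spawning, so a
single integer seed reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignments import ElementAlignment
from .codon import SENSE_CODONS, CodonAlignment, CodonModel
from .errors import DataError, InvalidParameterError
from .phylo import GTRModel, NeutralModel
from .trees import Phylogeny

__all__ = [
    "DIURNAL_TIPS", "NOCTURNAL_TIPS", "OUTGROUP", "fixture_tree",
    "default_neutral_model", "RegimeSpec", "simulate_alignment",
    "simulate_codon_alignment", "simulate_annotation_landscape", "Landscape",
]

DIURNAL_TIPS = ("burrowing_owl", "hawk_owl", "snowy_owl")
NOCTURNAL_TIPS = ("long_eared_owl", "eagle_owl", "spotted_owl", "barn_owl")
OUTGROUP = "cuckoo_roller"

# Default fixture branch lengths (substitutions/site under the neutral
# model): tips 0.05, internal branches 0.03, outgroup stem 0.3 — detectable
# but unsaturated divergence, total tree length ~0.83.
_TIP_LEN, _INT_LEN, _OUT_LEN = 0.05, 0.03, 0.3

_STRIGINAE = {
    "hawk-burrowing": "(long_eared_owl:{t},(hawk_owl:{t},burrowing_owl:{t}):{i}):{i}",
    "longeared-hawk": "(burrowing_owl:{t},(long_eared_owl:{t},hawk_owl:{t}):{i}):{i}",
    "longeared-burrowing": "(hawk_owl:{t},(long_eared_owl:{t},burrowing_owl:{t}):{i}):{i}",
}


def fixture_tree(arrangement: str = "hawk-burrowing") -> Phylogeny:
    """The eight-tip study phylogeny with diurnal foreground tips.

    Snowy owl and eagle owl are sisters, spotted owl joins that pair, barn
    owl is sister to all other (strigid) owls, and the cuckoo roller roots
    the tree. The placement of the long-eared owl / hawk owl / burrowing
    owl subclade is configurable via ``arrangement``.
    """
    if arrangement not in _STRIGINAE:
        raise InvalidParameterError(
            f"arrangement must be one of {sorted(_STRIGINAE)}")
    sub = _STRIGINAE[arrangement].format(t=_TIP_LEN, i=_INT_LEN)
    newick = (
        f"(((((snowy_owl:{_TIP_LEN},eagle_owl:{_TIP_LEN}):{_INT_LEN},"
        f"spotted_owl:{_TIP_LEN}):{_INT_LEN},{sub}):{_INT_LEN},"
        f"barn_owl:{_TIP_LEN}):{_INT_LEN},{OUTGROUP}:{_OUT_LEN});"
    )
    return Phylogeny.from_newick(newick, foreground=DIURNAL_TIPS,
                                 outgroup=OUTGROUP)


def default_neutral_model(tree: Phylogeny | None = None) -> NeutralModel:
    """Synthetic neutral reference: avian-like composition, transition bias."""
    tree = fixture_tree() if tree is None else tree
    gtr = GTRModel(np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
                   np.array([0.29, 0.21, 0.21, 0.29]))
    return NeutralModel(gtr, tree)


@dataclass
class RegimeSpec:
    """A substitution-rate regime: per-branch multipliers of neutral lengths."""

    name: str
    multipliers: dict[int, float]
    length: int = 200
    count: int = 1

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()):
            raise InvalidParameterError("rate multipliers must be positive")
        if self.length < 1 or self.count < 0:
            raise InvalidParameterError("length must be >=1 and count >=0")

    def multiplier_array(self, tree: Phylogeny) -> np.ndarray:
        mult = np.ones(tree.n_nodes)
        for node, m in self.multipliers.items():
            mult[int(node)] = m
        return mult

    @classmethod
    def neutral(cls, length=200, count=1):
        return cls("neutral", {}, length, count)

    @classmethod
    def conserved(cls, tree: Phylogeny, r1=0.3, length=200, count=1):
        mult = {int(b): r1 for b in tree.branches}
        return cls("conserved", mult, length, count)

    @classmethod
    def diurnal_accelerated(cls, tree: Phylogeny, r1=0.3, r2=2.0,
                            length=200, count=1):
        mult = {int(b): r1 for b in tree.branches}
        for b in tree.foreground:
            mult[int(b)] = r2
        return cls("diurnal_accelerated", mult, length, count)


def _evolve_states(tree: Phylogeny, P_by_node: np.ndarray, root_freqs,
                   n_sites: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    n_states = len(root_freqs)
    states = {tree.root: rng.choice(n_states, size=n_sites, p=root_freqs)}
    for node in tree.postorder[::-1]:
        node = int(node)
        if node == tree.root:
            continue
        parent_states = states[int(tree.parent[node])]
        child = np.empty(n_sites, dtype=np.int64)
        P = P_by_node[node]
        for s in range(n_states):
            idx = np.flatnonzero(parent_states == s)
            if idx.size:
                child[idx] = rng.choice(n_states, size=idx.size, p=P[s])
        states[node] = child
    return states


def simulate_alignment(tree: Phylogeny, model: NeutralModel | GTRModel,
                       regime: RegimeSpec, seed: int,
                       id_prefix: str | None = None) -> list[ElementAlignment]:
    """Simulate ``regime.count`` nucleotide elements along the tree.

    Root states are drawn from the stationary frequencies and propagated
    with P(branch length x regime multiplier). Deterministic given seed.
    """
    gtr = model.gtr if isinstance(model, NeutralModel) else model
    mult = regime.multiplier_array(tree)
    P = gtr.transitions(tree.lengths * mult)
    prefix = id_prefix or regime.name
    seeds = np.random.SeedSequence(seed).spawn(regime.count)
    out = []
    for k in range(regime.count):
        rng = np.random.default_rng(seeds[k])
        states = _evolve_states(tree, P, gtr.pi, regime.length, rng)
        seqs = {tree.names[int(i)]:
                "".join("ACGT"[s] for s in states[int(i)]) for i in tree.tips}
        out.append(ElementAlignment(f"{prefix}_{k:04d}", seqs))
    return out


def simulate_codon_alignment(tree: Phylogeny, kappa: float, omega_map,
                             n_codons: int, seed: int,
                             codon_freqs=None, gene_id: str = "gene",
                             site_classes=None) -> CodonAlignment:
    """Simulate an in-frame codon alignment with branch-class omegas.

    ``omega_map`` maps 'foreground'/'background' to omega, optionally with
    a 'nodes' entry ({tip or node name: omega}) overriding single branches.
    ``site_classes`` optionally lists (proportion, omega_fg, omega_bg)
    triples for site-heterogeneous (branch-site style) simulation; it
    overrides omega_map's foreground/background entries per site class.
    No stop codons are ever emitted (the state space is the 61 sense codons).
    """
    if codon_freqs is None:
        codon_freqs = np.full(61, 1.0 / 61)
    omega_fg = omega_map.get("foreground")
    omega_bg = omega_map.get("background")
    overrides = {}
    for name, w in (omega_map.get("nodes") or {}).items():
        idx = [i for i in range(tree.n_nodes) if tree.names[i] == name]
        if not idx:
            raise InvalidParameterError(f"unknown branch {name!r}")
        overrides[idx[0]] = float(w)
    if site_classes is None:
        site_classes = [(1.0, omega_fg, omega_bg)]
    for _, wf, wb in site_classes:
        if wf is None or wb is None or wf < 0 or wb < 0:
            raise InvalidParameterError("omega values must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    props = np.array([p for p, _, _ in site_classes], dtype=float)
    props = props / props.sum()
    assignment = rng.choice(len(site_classes), size=n_codons, p=props)
    columns = np.empty((len(tree.tips), n_codons), dtype=np.int64)
    tip_list = [int(i) for i in tree.tips]
    for ci, (_, wf, wb) in enumerate(site_classes):
        idx = np.flatnonzero(assignment == ci)
        if not idx.size:
            continue
        P = np.empty((tree.n_nodes, 61, 61))
        models: dict[float, CodonModel] = {}
        for node in range(tree.n_nodes):
            w = overrides.get(node,
                              wf if node in tree.foreground else wb)
            if w not in models:
                models[w] = CodonModel(kappa, w, codon_freqs)
            P[node] = models[w].transition(tree.lengths[node])
        states = _evolve_states(tree, P, codon_freqs, idx.size, rng)
        for row, tip in enumerate(tip_list):
            columns[row, idx] = states[tip]
    seqs = {tree.names[tip]:
            "".join(SENSE_CODONS[c] for c in columns[row])
            for row, tip in enumerate(tip_list)}
    return CodonAlignment(gene_id, seqs)


# -- annotated toy chromosome with a planted enrichment ------------------


@dataclass
class Landscape:
    """A simulated study: annotation, elements, truth labels, GO map."""

    genes: pd.DataFrame          # gene, chrom, start, end, strand, tss
    elements: pd.DataFrame       # chrom, start, end, element
    go_map: pd.DataFrame         # id, go (gene->GO rows)
    labels: pd.DataFrame         # element, regime, gene (placement gene)
    chrom_sizes: dict[str, int]
    planted_term: str
    alignments: list[ElementAlignment] = field(default_factory=list)


def simulate_annotation_landscape(
        tree: Phylogeny, model: NeutralModel, seed: int,
        n_genes: int = 25, n_elements: int = 400, chrom_length: int = 40_000_000,
        element_length: int = 200, planted_term: str = "GO:PLANTED",
        n_terms: int = 15, n_planted_genes: int = 5, effect: float = 0.8,
        r1: float = 0.3, r2: float = 2.0) -> Landscape:
    """Toy chromosome: genes with TSSs, elements inside regulatory space,
    flat GO annotations, and a planted acceleration signal.

    Elements placed near genes annotated with ``planted_term`` receive the
    diurnal-accelerated regime with probability ``effect``; all other
    elements evolve under the conserved regime. True regimes are recorded
    for downstream truth checking.
    """
    if n_genes < 1 or n_elements < 1:
        raise InvalidParameterError("counts must be positive")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss[0])
    gene_len = 5_000
    slot = chrom_length // n_genes
    if slot < gene_len + 20 * element_length:
        raise DataError("chromosome too short to place genes without overlap")
    genes = []
    for g in range(n_genes):
        lo = g * slot
        start = int(lo + rng.integers(slot // 4, slot // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + gene_len - 1
        genes.append((f"gene{g:03d}", "chr1", start, start + gene_len,
                      strand, tss))
    genes_df = pd.DataFrame(
        genes, columns=["gene", "chrom", "start", "end", "strand", "tss"])

    planted_genes = set(rng.choice(genes_df["gene"], size=n_planted_genes,
                                   replace=False))
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    go_rows = []
    for gene in genes_df["gene"]:
        for term in rng.choice(terms, size=rng.integers(1, 4), replace=False):
            go_rows.append((gene, term))
        if gene in planted_genes:
            go_rows.append((gene, planted_term))
    go_df = pd.DataFrame(go_rows, columns=["id", "go"])

    # elements scattered around gene TSSs, inside the (untruncated) 1 Mb
    # domain but outside the gene body, >= 50 bp by construction
    el_rows, label_rows = [], []
    order = rng.integers(0, n_genes, size=n_elements)
    for e, gi in enumerate(order):
        grow = genes_df.iloc[gi]
        offset = int(rng.integers(2_000, min(1_000_000, slot // 2 - gene_len)))
        side = -1 if rng.random() < 0.5 else 1
        pos = int(grow["tss"] + side * offset)
        pos = max(0, min(pos, chrom_length - element_length))
        name = f"cnee{e:05d}"
        el_rows.append(("chr1", pos, pos + element_length, name))
        accelerated = (grow["gene"] in planted_genes
                       and rng.random() < effect)
        label_rows.append((name, "diurnal_accelerated" if accelerated
                           else "conserved", grow["gene"]))
    elements_df = pd.DataFrame(el_rows,
                               columns=["chrom", "start", "end", "element"])
    labels_df = pd.DataFrame(label_rows, columns=["element", "regime", "gene"])

    regimes = {
        "conserved": RegimeSpec.conserved(tree, r1=r1, length=element_length),
        "diurnal_accelerated": RegimeSpec.diurnal_accelerated(
            tree, r1=r1, r2=r2, length=element_length),
    }
    el_seeds = np.random.SeedSequence(ss[1].entropy, spawn_key=(1,)
                                      ).spawn(n_elements)
    alignments = []
    for e in range(n_elements):
        regime = regimes[labels_df.iloc[e]["regime"]]
        aln = simulate_alignment(tree, model,
                                 RegimeSpec(regime.name, regime.multipliers,
                                            element_length, 1),
                                 seed=el_seeds[e].generate_state(1)[0] % (2**31),
                                 id_prefix="x")[0]
        row = elements_df.iloc[e]
        alignments.append(ElementAlignment(
            row["element"], aln.seqs, chrom=row["chrom"],
            start=int(row["start"]), end=int(row["end"])))
    return Landscape(genes_df, elements_df, go_df, labels_df,
                     {"chr1": chrom_length}, planted_term, alignments)
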