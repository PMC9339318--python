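"""Config-driven orchestration of the full study design.

``run_pipeline`` sequences the stages on synthetic or user-supplied data:
neutral-model fit, optional conserved-element discovery, rate-shift
fitting with Bayes-factor candidate calling, codon selection tests,
the subscale LRT with its length-stratified summary, and the rank-based
GO enrichment. Every stage writes a TSV; a JSON manifest records the
package version, all thresholds actually used, per-stage child seeds and
per-element failures. One global seed fans out deterministically
(``numpy.random.SeedSequence(seed, spawn_key=(stage,))``), so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignments import write_element_fasta, write_bed
from .codon import (apply_fdr, fit_branch_model, fit_branch_site_model)
from .conserved import decode_conserved_segments, filter_min_length
from .enrichment import (GeneAnnotation, RankScore, assign_elements,
                         fwer_adjust, one_closest_domains, rank_statistic,
                         enrichment_table)
from .errors import OwlAccelError
from .phylo import fit_neutral_model
from .rateshift import (RateShiftConfig, add_subscale_fdr, fit_rate_shift,
                        fit_subscale_lrt, score_branch_posteriors,
                        summarize_subscale_by_length)
from .simulate import (DIURNAL_TIPS, OUTGROUP, RegimeSpec, default_neutral_model,
                       fixture_tree, simulate_alignment,
                       simulate_annotation_landscape, simulate_codon_alignment)
from .trees import Phylogeny

log = logging.getLogger("owlaccel")

__all__ = ["RunConfig", "run_pipeline", "write_reports"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; thresholds default to the study's."""

    output_dir: str = "owlaccel_run"
    seed: int = 1

    # input paths (None -> synthetic stage generates the data)
    tree_path: str | None = None
    elements_dir: str | None = None
    genes_path: str | None = None
    go_map_path: str | None = None

    foreground: tuple = DIURNAL_TIPS
    outgroup: str = OUTGROUP

    # candidate-calling thresholds
    bf1_min: float = 10.0
    bf2_min: float = 1.0
    pp_min: float = 0.8
    min_diurnal: int = 2
    fdr_alpha: float = 0.05
    min_len: int = 50

    # quadrature / permutation sizes
    n_r1: int = 12
    n_r2: int = 12
    score_n_r1: int = 4
    score_n_r2: int = 4
    n_perm: int = 1000

    # synthetic-landscape parameters
    n_genes: int = 25
    n_planted_genes: int = 5
    n_elements: int = 400
    element_length: int = 200
    effect: float = 0.8
    r1: float = 0.3
    r2: float = 2.0
    n_codon_genes: int = 0
    n_codons: int = 300
    neutral_sites: int = 10_000

    # stage toggles
    find_cnees: bool = False
    run_rate_shift: bool = True
    run_subscale: bool = True
    run_enrichment: bool = True
    full_fit_elements: int | None = None   # cap on full M0/M1/M2 fits

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _stage_seed(config: RunConfig, stage: int) -> int:
    ss = np.random.SeedSequence(config.seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: getattr(config, k) for k in
                       ("bf1_min", "bf2_min", "pp_min", "min_diurnal",
                        "fdr_alpha", "min_len")},
        "quadrature": {"n_r1": config.n_r1, "n_r2": config.n_r2,
                       "score_n_r1": config.score_n_r1,
                       "score_n_r2": config.score_n_r2},
        "n_perm": config.n_perm,
        "stages": {},
        "failures": [],
    }

    # -- stage 0: tree ---------------------------------------------------
    if config.tree_path:
        tree = Phylogeny.read(config.tree_path, foreground=config.foreground,
                              outgroup=config.outgroup)
    else:
        tree = fixture_tree()
    tree.write(out / "tree.nwk")
    manifest["stages"]["tree"] = {"tips": sorted(tree.tip_names),
                                  "foreground": tree.foreground_names}

    # -- stage 1: neutral model -----------------------------------------
    seed1 = _stage_seed(config, 1)
    truth_model = default_neutral_model(tree)
    neutral_aln = simulate_alignment(
        tree, truth_model,
        RegimeSpec.neutral(length=config.neutral_sites, count=1),
        seed=seed1, id_prefix="neutral_sites")[0]
    model = fit_neutral_model(neutral_aln, tree)
    with open(out / "neutral_model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    manifest["stages"]["neutral_model"] = {
        "seed": seed1, "sites": config.neutral_sites,
        "loglik": float(model.loglik),
        "tree_length": float(model.tree.total_length)}
    log.info("neutral model fitted (lnL=%.1f)", model.loglik)

    # -- stage 2: landscape ----------------------------------------------
    seed2 = _stage_seed(config, 2)
    landscape = simulate_annotation_landscape(
        tree, model, seed=seed2, n_genes=config.n_genes,
        n_planted_genes=config.n_planted_genes,
        n_elements=config.n_elements, element_length=config.element_length,
        effect=config.effect, r1=config.r1, r2=config.r2)
    landscape.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    landscape.elements.to_csv(out / "elements.bed", sep="\t", index=False,
                              header=False)
    landscape.go_map.to_csv(out / "go_map.tsv", sep="\t", index=False)
    landscape.labels.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in landscape.alignments[: min(20, len(landscape.alignments))]:
        write_element_fasta(aln, aln_dir / f"{aln.id}.fa")
    manifest["stages"]["landscape"] = {
        "seed": seed2, "n_genes": config.n_genes,
        "n_elements": config.n_elements,
        "planted_term": landscape.planted_term}

    # -- stage 3: conserved-element discovery (optional) -----------------
    if config.find_cnees:
        segments = []
        for aln in landscape.alignments:
            try:
                segs = filter_min_length(
                    decode_conserved_segments(aln, model), config.min_len)
            except OwlAccelError as exc:
                manifest["failures"].append({"stage": "find_cnees",
                                             "element": aln.id,
                                             "error": str(exc)})
                continue
            segments.extend(s.to_bed6(aln.id) for s in segs)
        write_bed(segments, out / "conserved_segments.bed")
        manifest["stages"]["find_cnees"] = {"n_segments": len(segments)}

    # -- stage 4: rate shift ---------------------------------------------
    rs_rows = []
    if config.run_rate_shift:
        cfgs = RateShiftConfig.triple(tree, n_r1=config.n_r1,
                                      n_r2=config.n_r2)
        cap = config.full_fit_elements or len(landscape.alignments)
        for aln in landscape.alignments[:cap]:
            try:
                r = fit_rate_shift(aln, model, cfgs=cfgs, tree=tree,
                                   min_length=config.min_len,
                                   bf1_min=config.bf1_min,
                                   bf2_min=config.bf2_min,
                                   pp_min=config.pp_min,
                                   min_diurnal=config.min_diurnal)
            except OwlAccelError as exc:
                log.warning("rate-shift skipped %s: %s", aln.id, exc)
                manifest["failures"].append({"stage": "rate_shift",
                                             "element": aln.id,
                                             "error": str(exc)})
                continue
            row = {"element": r.element, "class": r.element_class,
                   "length": r.length,
                   "logml_m0": r.logml["M0"], "logml_m1": r.logml["M1"],
                   "logml_m2": r.logml["M2"], "logbf1": r.logbf1,
                   "logbf2": r.logbf2, "r1_hat": r.r1_hat,
                   "r2_hat": r.r2_hat, "candidate": r.candidate}
            for tip in sorted(tree.foreground_names):
                row[f"pp_{tip}"] = r.pp_m2[tip]
            rs_rows.append(row)
        rs_df = pd.DataFrame(rs_rows)
        rs_df.to_csv(out / "rate_shift.tsv", sep="\t", index=False,
                     float_format="%.6g")
        manifest["stages"]["rate_shift"] = {
            "n_elements": len(rs_rows),
            "n_candidates": int(rs_df["candidate"].sum()) if rs_rows else 0}
        log.info("rate shift: %d candidates / %d elements",
                 manifest["stages"]["rate_shift"]["n_candidates"],
                 len(rs_rows))

    # -- stage 5: codon selection tests (optional) -----------------------
    if config.n_codon_genes > 0:
        seed5 = _stage_seed(config, 5)
        gene_seeds = np.random.SeedSequence(seed5).spawn(config.n_codon_genes)
        codon_rows = []
        for g in range(config.n_codon_genes):
            accelerated = g < max(1, config.n_codon_genes // 3)
            omega_fg = 2.0 if accelerated else 0.2
            aln = simulate_codon_alignment(
                tree, kappa=2.0,
                omega_map={"foreground": omega_fg, "background": 0.2},
                n_codons=config.n_codons,
                seed=int(gene_seeds[g].generate_state(1)[0] % (2 ** 31)),
                gene_id=f"cds{g:03d}")
            for fitter in (fit_branch_model, fit_branch_site_model):
                res = fitter(aln, tree)
                codon_rows.append(res)
        apply_fdr([r for r in codon_rows if r.test == "branch"],
                  alpha=config.fdr_alpha)
        apply_fdr([r for r in codon_rows if r.test == "branch_site"],
                  alpha=config.fdr_alpha)
        cdf = pd.DataFrame([{
            "gene": r.gene, "test": r.test, "lnL0": r.lnL_null,
            "lnL1": r.lnL_alt, "w_bg": r.omega_background,
            "w_fg": r.omega_foreground, "LRT": r.lrt, "df": r.df,
            "p": r.p, "p_adj": r.p_adj, "accelerated": r.accelerated}
            for r in codon_rows])
        cdf.to_csv(out / "codon_tests.tsv", sep="\t", index=False,
                   float_format="%.6g")
        manifest["stages"]["codon_tests"] = {
            "seed": seed5, "n_genes": config.n_codon_genes,
            "n_accelerated": int(cdf["accelerated"].fillna(False).sum())}

    # -- stage 6: subscale LRT -------------------------------------------
    sub_results = []
    if config.run_subscale:
        for aln in landscape.alignments:
            try:
                sub_results.append(fit_subscale_lrt(aln, model, tree=tree,
                                                    element_class="owl_cnee"))
            except OwlAccelError as exc:
                manifest["failures"].append({"stage": "subscale",
                                             "element": aln.id,
                                             "error": str(exc)})
        add_subscale_fdr(sub_results, alpha=config.fdr_alpha)
        sdf = pd.DataFrame([{
            "element": r.element, "class": r.element_class,
            "length": r.length, "scale_null": r.scale_null,
            "scale_fg": r.scale_fg, "scale_bg": r.scale_bg,
            "subscale": r.subscale, "p": r.p, "q": r.q,
            "significant": r.significant} for r in sub_results])
        sdf.to_csv(out / "subscale.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary = summarize_subscale_by_length(sub_results)
        summary.to_csv(out / "subscale_by_length.tsv", sep="\t", index=False,
                       float_format="%.6g")
        manifest["stages"]["subscale"] = {
            "n_elements": len(sub_results),
            "n_significant": int(sum(bool(r.significant)
                                     for r in sub_results))}

    # -- stage 7: enrichment ---------------------------------------------
    if config.run_enrichment:
        seed7 = _stage_seed(config, 7)
        pp_by_element: dict[str, dict] = {}
        full_pp = {row["element"]: row for row in rs_rows}
        scores = []
        for aln in landscape.alignments:
            try:
                pp = score_branch_posteriors(aln, model, tree=tree,
                                             n_r1=config.score_n_r1,
                                             n_r2=config.score_n_r2)
            except OwlAccelError as exc:
                manifest["failures"].append({"stage": "enrichment",
                                             "element": aln.id,
                                             "error": str(exc)})
                continue
            pp_by_element[aln.id] = pp
            scores.append(RankScore(aln.id, rank_statistic(pp, tree)))
        genes = [GeneAnnotation(r.gene, r.chrom, int(r.start), int(r.end),
                                r.strand)
                 for r in landscape.genes.itertuples()]
        domains = one_closest_domains(genes, landscape.chrom_sizes)
        elements = [(r.chrom, int(r.start), int(r.end), r.element)
                    for r in landscape.elements.itertuples()]
        gene_of = assign_elements(elements, domains)
        gene_go: dict[str, set] = {}
        for r in landscape.go_map.itertuples():
            gene_go.setdefault(r.id, set()).add(r.go)
        annotations = {e: gene_go.get(g, set()) for e, g in gene_of.items()}
        annotations = {e: ts for e, ts in annotations.items() if ts}
        rows = fwer_adjust(scores, annotations, n_perm=config.n_perm,
                           seed=seed7)
        edf = enrichment_table(rows)
        edf.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        pd.DataFrame([{"element": e, "gene": g} for e, g
                      in sorted(gene_of.items())]).to_csv(
            out / "element_gene.tsv", sep="\t", index=False)
        pd.DataFrame([{"element": s.element, "score": s.score}
                      for s in scores]).to_csv(
            out / "rank_scores.tsv", sep="\t", index=False,
            float_format="%.6g")
        manifest["stages"]["enrichment"] = {
            "seed": seed7, "n_scored": len(scores),
            "n_terms": len(rows),
            "top_term": edf.iloc[0]["go"] if len(edf) else None,
            "top_fwer": float(edf.iloc[0]["fwer"]) if len(edf) else None}
        log.info("enrichment: top term %s (FWER=%s)",
                 manifest["stages"]["enrichment"]["top_term"],
                 manifest["stages"]["enrichment"]["top_fwer"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def write_reports(output_dir, plots: bool = False) -> list[str]:
    """Re-derive the human-facing report tables from a finished run.

    Produces the candidate table (element, logBFs, rates, per-tip
    posteriors), which always satisfies the calling rule by construction,
    and returns the list of files written. Empty runs yield headers-only
    files and exit successfully.
    """
    out = Path(output_dir)
    written = []
    rs_path = out / "rate_shift.tsv"
    cols = ["element", "class", "length", "logbf1", "logbf2",
            "r1_hat", "r2_hat", "candidate"]
    if rs_path.exists():
        df = pd.read_csv(rs_path, sep="\t")
        pp_cols = [c for c in df.columns if c.startswith("pp_")]
        cand = df[df.get("candidate", False) == True]  # noqa: E712
        cand = cand[[c for c in cols if c in df.columns] + pp_cols]
    else:
        cand = pd.DataFrame(columns=cols)
    path = out / "candidates.tsv"
    cand.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(str(path))
    if plots and rs_path.exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = pd.read_csv(rs_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df["logbf1"], df["logbf2"], s=8,
                   c=df["candidate"].map({True: "crimson", False: "gray"}))
        ax.axvline(10, ls="--", lw=0.8)
        ax.axhline(1, ls="--", lw=0.8)
        ax.set_xlabel("logBF1 (M1 vs M0)")
        ax.set_ylabel("logBF2 (M1 vs M2)")
        fig.tight_layout()
        fig.savefig(out / "bayes_factors.png", dpi=150)
        written.append(str(out / "bayes_factors.png"))
    return written
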