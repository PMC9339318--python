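# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `owlaccel`, in the package's own terms. Nothing here reports a
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Phylogenetic substrate

The unit of analysis is a per-element multi-species alignment over an
eight-tip rooted owl phylogeny whose three diurnal species (burrowing owl,
northern hawk owl, snowy owl) form the foreground branch set and whose
outgroup is the cuckoo roller. Likelihoods use Felsenstein pruning over
unique site patterns with per-pattern rescaling, so the computed
log-likelihood is exact (no underflow approximation). `N` and `-` are
treated as missing data (all-ones partial vectors); soft-masked lowercase
is uppercased on read; an all-missing column contributes exactly zero.
Under the reversible models used throughout, the likelihood is invariant
to root placement, which is how the package honours analyses that are
conventionally run on unrooted trees: it computes on the rooted topology
without a separate unrooted code path.

The neutral reference is a GTR model (6 exchangeabilities, 4 frequencies,
generator normalised to one expected substitution per unit branch length)
plus branch lengths, fitted by bounded L-BFGS-B on log-transformed rates
and branch lengths with additive-log-ratio frequencies, from two fixed
starting points (equal exchangeabilities, and a transition-biased start);
convergence tolerance 1e-8 on the objective. Fourfold-degenerate sites are
extracted with a strict cross-species rule: a codon column qualifies only
if every taxon's codon is ungapped and unambiguous, the first two codon
positions agree across all taxa, and that prefix defines a fourfold
family. On 20 kb of simulated neutral data the fit recovers base
frequencies within ±0.02 and total tree length within 10% (asserted in the
test suite). Fitting a taxon subset (e.g. the four nocturnal owls only)
goes through `Phylogeny.subtree`.

## Conserved-element HMM

A two-state HMM over alignment columns: the conserved state emits under
the neutral model with all branch lengths scaled by ρ, the neutral state
with ρ = 1. Defaults ρ = 0.3, switch probabilities μ = 1/45
(conserved→neutral) and ν = 1/100, posterior cutoff 0.5 — magnitudes
customary for this kind of segmentation; all are configurable, and ρ can
optionally be refined by a bounded 1-D likelihood maximisation
(`refine_rho`). μ and ν are not re-estimated (no EM) — a documented
simplification; the acceptance checks rely on planted simulations, not on
tuned transition probabilities. Maximal runs of columns with conserved
posterior ≥ cutoff become segments; segments shorter than 50 bp are
discarded. The noncoding restriction is implemented by subtracting gene
intervals from the searchable space (`subtract_intervals`) before
decoding. An optional exclusion mask can remove regions overlapping a
prior element set; it is off by default because the correct behaviour is
underdetermined.

## Codon selection tests

Goldman–Yang-style 61×61 codon generators: zero rate for multi-nucleotide
changes, factor κ for transitions, ω for nonsynonymous changes, target
codon frequency factor (F3×4 from the alignment, +1/2 smoothing). Within a
fit or simulation, all ω-classes share one normalisation — the expected
rate of the ω = 1 matrix with the same κ and frequencies — so ω > 1 means
genuinely faster evolution on the same time scale rather than a
recomposed substitution spectrum. (The standalone matrix constructor
`build_codon_matrix` normalises to unit expected rate, the usual
single-model convention; the shared scale only matters when classes are
mixed.)

Nuisance treatment: κ and a single tree-scale factor are estimated once
per gene under a one-ω model and held fixed in the null and alternative
fits; branch lengths are the input tree's, rescaled by that one factor and
never re-optimised per branch. This is the "shared κ/branch-length
treatment" appropriate at this scale, and the empirical type-I error of
the tests under it is checked directly (below).

* **Branch model** — null: one ω; alternative: ω_fg shared across the
  three diurnal tips (a per-tip option exists) vs ω_bg; LRT with df = 1,
  χ²₁ p-values.
* **Branch-site Model A** — classes 0 (ω₀ both), 1 (neutral both),
  2a (bg ω₀, fg ω₂), 2b (bg 1, fg ω₂); proportions parameterised as
  q = p₀+p₁, f = p₀/(p₀+p₁). The null fixes ω₂ = 1, placing it on the
  boundary of the alternative space, so p-values use the asymptotically
  correct ½χ²₀ + ½χ²₁ mixture (df reported as 1); plain χ²₁ would be
  conservative by about half. The alternative is seeded from ω₂ ∈
  {1.5, 4, 16} and optimised from the best seed.
* **Per-branch screen** — a two-ratio LRT for each diurnal tip separately,
  Holm–Bonferroni across the gene's foreground branches; the same test is
  applied to every background branch (Holm within that family), and a gene
  is *foreground specific* when ≥ 2 diurnal branches are individually
  significant and no background branch is flagged. This captures the
  decision role of an adaptive per-branch method without reimplementing
  its ω-distribution complexity selection.

Measured operating characteristics on the fixture tree (fixed seeds, in
the test suite): branch-model type-I error 0.080 and branch-site 0.045 at
nominal α = 0.05 over 200 null replicates of 100 codons; subscale LRT
0.038 over 500 replicates. Branch-model recovery at 300 codons with truth
ω_fg = 2.0, ω_bg = 0.2: median ω̂_fg within [1.5, 2.6] and rejection in
≥ 80% of 20 replicates. The branch-site test's absolute power is modest on
this design — with 10% of sites at fg ω₂ = 4 and diurnal tip branches of
0.05 substitutions/site, measured power is ≈ 20–25% (9/40 seeds), even
though an oracle LRT with the true mixture weights would reject ~75% of
the time: with so few expected foreground substitutions the free null
absorbs most of the signal, the known behaviour of Model A on short
foreground branches. The suite therefore asserts the defensible
properties — rejection well above the nominal level under signal, mean LRT
under signal far exceeding the null — rather than a high absolute power
this design cannot deliver.

## Rate-shift model and Bayes factors

Each element has one latent state per branch: neutral (rate r₀ = 1),
conserved (r₁ < 1), accelerated (r₂ > r₁), with a Markov prior along the
tree — root neutral; neutral→conserved probability α = 0.5 per branch;
conserved→accelerated probability β per branch where acceleration is
allowed; no reversals. M0 allows acceleration nowhere, M1 only on the
three diurnal tips (never the outgroup), M2 on any branch.

β defaults to 0.2. The choice is structural, not cosmetic: for an element
whose data put probability ≈ 1 on the "diurnal tips accelerated"
configuration, logBF2 = logML(M1) − logML(M2) is bounded near
n_bg · log(1/(1−β)) — the prior cost M2 pays for *not* accelerating each
of its extra allowed branches. With 11 background branches this bound is
≈ 0.6 at β = 0.05 (the logBF2 ≥ 1 rule could never fire) and ≈ 2.4 at
β = 0.2. Measured on pilot simulations: cleanly diurnal-accelerated
elements reach logBF2 ≈ 1.8 and conserved elements logBF1 ≈ −0.5.

Because the no-reversal prior admits only a few thousand configurations on
an eight-tip tree (3,676 under M2), the configuration shared by all
columns of an element is marginalised **exactly**: a tree-shaped dynamic
program enumerates subtree configurations once per topology, lifts partial
likelihood vectors through each branch with the state-specific transition
matrix, and combines children multiplicatively, evaluating every
configuration at every quadrature node simultaneously. A per-column
(site-independent) mixture would factorise more cheaply but pays the shift
prior per column and provably cannot reach logBF1 ≥ 10 on element-scale
signals, so it is not used. The implementation equals brute-force
enumeration over admissible state vectors to 1e-8 on small trees (tested),
and per-branch acceleration posteriors come from the same joint posterior
over (configuration × rate grid).

Priors and quadrature: r₁ ~ Uniform(0.01, 1), r₂ | r₁ ~ Uniform(r₁, 4];
the marginal likelihood uses a midpoint rule on 12 × 12 log-spaced nodes
(M0 integrates r₁ only). The grid scan runs in float32 (the Bayes factors
are thresholded at whole log units; the float64 path is kept for the
single-point oracle), chunked over grid nodes to stay cache-resident.
r̂₁, r̂₂ are posterior means under M1. A coarse-grid scoring mode
(`score_branch_posteriors`, default 4 × 4) provides the per-branch
posteriors for ranking large element sets; branch posteriors are
insensitive to fine rate resolution.

Candidate rule (exact thresholds, inclusive as stated): logBF1 ≥ 10,
logBF2 ≥ 1, and M2 acceleration posterior > 0.8 on at least two of the
three diurnal tips. Measured operating point on 100 simulated 200-bp
elements (70 conserved r₁ = 0.3, 30 with r₂ = 2.0 on the diurnal tips):
per-element detection probability close to 0.8 (batches of 30 range
roughly 0.73–0.87 across seeds) with false-positive rate ≤ 0.02; the
suite asserts sensitivity ≥ 0.8 and FPR ≤ 0.02 at its fixed seeds, and
the acceptance script recomputes both for any seed.

## Subscale LRT and length-stratified comparison

Null: one scale multiplying all neutral branch lengths (1-D bounded
optimisation); alternative: separate foreground (diurnal-tip) and
background scales (L-BFGS-B, started from the null optimum); LRT df = 1.
Genes and CNEEs both enter as plain nucleotide alignments — codon
structure is deliberately ignored so that coding and noncoding
acceleration magnitudes are measured on the same scale. BH correction runs
within each element class (genes, avian CNEEs, owl CNEEs), and
significance requires subscale > 1 **and** q < 0.05. The binned summary
reports count, median and quartiles of log10(subscale) per class and
length interval (default bin edges 0, 200, 400, 600, 800, 1000, ∞),
excluding genes > 1,000 bp and avian CNEEs < 200 bp so that all classes
are compared over a shared length range.

## Ranking and enrichment

The ranking statistic for noncoding elements is
D = Σ_diurnal (pp_b − pp_anc(b)) − Σ_background (pp_b − pp_anc(b)), with
pp the M2 acceleration posterior and pp_anc the posterior of the parent
branch. The background sum covers all non-foreground branches except the
outgroup tip and the root's own child branches; excluding root children is
forced by consistency — the root is constrained neutral (anc = 0 for its
children), and without the exclusion D would not vanish when every branch
carries the same posterior. A flag restricts the background to nocturnal
tip branches only, since the intended reading is ambiguous. Genes are
ranked by their LRT statistic; under the branch model only genes with
ω_bg < ω_fg are ranked.

One-Closest regulatory domains extend from each TSS (interval start on +,
end − 1 on −) to the midpoint toward the neighbouring TSS, at most 1 Mb
per side, clipped to the chromosome; elements are assigned to the domain
containing their midpoint (domains are disjoint, so the assignment is
unique; elements in inter-domain gaps stay unassigned). GO annotations are
flat (no graph propagation; an option exists but defaults off).

Per GO term, a two-sided Wilcoxon rank-sum test compares scores of
annotated elements against all others (ties mid-ranked; terms annotating
none or all elements are skipped). Small untied groups use the exact
distribution; otherwise a tie-corrected normal approximation with
continuity correction. FWER(term) is the fraction of score permutations
(annotations fixed) in which the smallest raw p across terms is ≤ the
term's observed p; observed and permuted p-values use the same vectorised
machinery so the comparison is like for like. Measured: raw p-values
uniform under the global null (KS p > 0.01 over 1,000 simulations), and
the family-wise rejection rate at 0.05 falls within [0.02, 0.09] over 200
global-null datasets.

## Synthetic data: what it does and does not emulate

The generator reproduces the *design* of the study: the fixture topology
(snowy + eagle owl sisters, spotted owl joining them, barn owl sister to
the other owls, cuckoo roller outgroup; the placement of the
long-eared/hawk/burrowing subclade is configurable across the three
resolutions, and results should be robust to the choice), branch lengths
of 0.05 for tips, 0.03 for internal branches and 0.3 for the outgroup stem
(detectable but unsaturated divergence, total ≈ 0.83 — no empirical branch
lengths are published for this tree), an avian-like base composition
(GC ≈ 0.42) with transition bias 4, and rate regimes r₁ = 0.3 / r₂ = 2.0
matched to the inference defaults. The annotated toy chromosome places
non-overlapping genes, scatters ≥ 50 bp elements within 1 Mb of gene TSSs,
assigns flat GO terms, and plants acceleration on elements near
planted-term genes with probability 0.8.

It does **not** emulate alignment error, indels, GC-biased gene
conversion, repeat structure, codon-usage bias beyond F3×4, or spatial
autocorrelation of conservation — so passing tests demonstrate that the
inference machinery is correct and calibrated under its model, not that
real-genome preprocessing artefacts are handled.

Problem sizes in the tests and the acceptance script (100 elements of
200 bp for the candidate operating point; 200–500 replicates for
calibrations; 10 end-to-end runs of 400 elements for planted-GO recovery;
4,000–20,000 sites for neutral-model fits) were chosen as the smallest
sizes at which the measured quantities are stable; the pipeline accepts
larger inputs unchanged.

## Reproducibility

Every stage derives its randomness from one integer seed through
`numpy.random.SeedSequence(seed, spawn_key=(stage,))`; identical
configuration and seed give byte-identical output files (tested). The run
manifest records the package version, all thresholds in force, per-stage
child seeds, and per-element failures (logged and skipped, never silently
dropped).

## Known limitations

* The exact configuration enumeration scales with the number of admissible
  state vectors; it is designed for trees of this size (≲ 12 tips), not
  for hundreds of taxa, where the count grows exponentially.
* The float32 grid scan bounds marginal-likelihood error well below the
  whole-log-unit Bayes-factor thresholds but would be inappropriate if
  Bayes factors near 0.01 mattered.
* Branch-site power on short foreground branches is intrinsically low (see
  above); negative branch-site results on this design are weak evidence of
  absence.
* The subscale LRT inherits the χ²₁ approximation; its calibration is
  verified empirically on the fixture tree only.
* μ/ν of the conserved-element HMM are fixed, not estimated; segment
  length distributions are therefore only as good as those defaults.
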