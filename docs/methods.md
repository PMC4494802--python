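# Methods

This note records the statistical model behind `nof1seq`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## The n-of-1 setting

All inference runs one patient sample against *frozen* summaries of a
reference cohort ("documentation by value").  The frozen archive holds, per
gene: the geometric mean of cohort counts (the median-of-ratios reference),
membership in the background set (zero raw counts in every cohort sample),
and the normal-tissue negative-binomial parameters; plus any trained
classifiers and build provenance.  Freezing makes later patients
prospectively processable and byte-reproducible: nothing about the cohort is
recomputed at analysis time.

### Normalization

Size factors follow the median-of-ratios convention: genes with any zero
cohort count get geometric mean 0 and never enter a ratio median, and a
ratio additionally requires a positive count in the sample being scaled
(otherwise shallow samples are dragged toward zero).  Cohort samples are
normalized jointly — tumor and normal share one normalization run — because
the frozen geometric means must describe the whole cohort a later patient is
compared against.  The add-on size factor for a new sample uses exactly the
same eligibility rule, which is what makes the add-on path consistent with
the cohort path to machine precision.

### Reliability filter

The expression cutoff is the 0.95 quantile (linear interpolation,
configurable via `--bg-quantile`) of the *patient's* log2(normalized+1)
values over the background genes.  Background genes are silent in every
reference sample, so whatever the patient shows there is noise: mapping
artifacts, contamination, index hopping.  The quantile is computed on the
patient side (not stored cohort-side) because the noise floor is a property
of the sample being analyzed; this choice is surfaced in the provenance
block.  The comparison is strict (`>`), so at quantile 1.0 the loudest
background gene itself never passes.

### Single-sample differential expression

With one tumor observation per gene there is no within-patient replication,
so the test asks: how surprising is this count under the frozen normal
model?  Per gene, normal samples give a mean `m` of normalized counts and a
method-of-moments dispersion `a = max((var − m)/m², 1e-8)` (ddof=1
variance).  The dispersion floor 1e-8 keeps the NB well-defined and reduces
to Poisson behavior for underdispersed genes.  No cross-gene shrinkage is
applied: moment estimates are transparent and directly testable, and with
few normal samples they are noticeably noisy — a known limitation that
mostly costs power for down-regulation (see below).  The two-sided p-value
doubles the smaller NB tail and caps at 1; on discrete counts this is
slightly conservative (the observed point mass enters both tails), which is
visible as a null rejection rate a little under nominal at low means.
Benjamini-Hochberg adjustment is used, with defaults adjusted p < 0.05 and
|lfc| ≥ 1 (pseudocount 1) for calling; both are configuration, not model.

An asymmetry worth knowing: with a single observation, an 8-fold *increase*
at mean ~100 sits ~19 null SDs out, but an 8-fold *decrease* only ~2.5 — NB
tails are not log-symmetric — so sensitivity claims here are stated for
up-spikes, and down-regulation at moderate dispersion is detected less
reliably.

### Classification

Nearest-shrunken-centroid models for receptor status (binary) and intrinsic
subtype (4-class).  Conventions: pooled within-class SD with `n − K` degrees
of freedom, `s0` = median of the per-gene pooled SDs, class scale
`m_k = sqrt(1/n_k + 1/n)`, priors `n_k/n`.  Shrinkage Δ is selected by
10-fold stratified cross-validation over a 30-point grid from 0 to
`max|d_kj|`; ties break toward the largest Δ (fewest genes), favoring the
sparser, more interpretable predictor.  At Δ=0 the classifier coincides
with a diagonal-covariance Gaussian discriminant, which is used as an
independent oracle in tests.  Genes with zero standardized scale
(`s_j + s0 = 0`) are never selected; a fully collapsed model falls back to
priors and is flagged uninformative.  Missing genes in a patient profile
are imputed with the overall centroid and warned about.  Receptor calls
report the argmax class with its probability; no probability threshold is
imposed.

### Pathway impact

Per pathway, signed edges (activation +1, inhibition −1; other relation
types weight 0 by default, configurable) form `β`, normalized per source
gene by its number of targets (floored at 1 so leaves never divide by
zero).  `PF = (I − B)^{-1} ΔE` is solved directly; a topology whose
smallest singular value of `I − B` falls below 1e-10 is excluded and
flagged rather than damped — explicit failure beats a silently distorted
number in a clinical report.  The perturbation null places the observed
nonzero fold changes on uniformly random distinct gene positions
(default 2000 draws, seed recorded in provenance); `pPERT` is two-sided
around the null median and floored at 1/n_boot.  An exhaustive-enumeration
mode with the same placement rule exists for exact testing on small
pathways.  `pNDE` is the hypergeometric upper tail over the reliable-gene
universe (the enrichment universe is the reliable set, matching what was
actually testable).  `pG = c − c ln c` combines the two, BH-adjusted across
pathways; activated/inhibited status follows the sign of `tA` for
significant pathways.

### Clinical rules

Variant keys are (chrom, pos 1-based, ref, alt) with the `chr` prefix
stripped; multi-allelic rows are split per alt before filtering.  A variant
is removed iff flagged common/no-known-medical-impact OR its population MAF
strictly exceeds 0.1; a missing MAF retains the variant, since absent
population data must not suppress a potentially actionable call.
Annotations attach only on exact four-field key equality — never
position-only.  The stated rule concerns single-nucleotide variants; indels
are joined by the same exact key and flagged as beyond the stated rule.
Fusion candidates are ingested, not discovered, and ranked by ascending
oncogenic p with absent values last (stable sort).

Drug matching applies an explicit action/direction table (inhibitor,
antagonist, antibody ↔ up-regulated target; agonist ↔ down-regulated;
other ↔ either, concordance not applicable).  Direction concordance is
required by default and can be disabled; the rule applied is printed in the
report so clinicians see it.  Only drugs with an approved flag ever match.
Ranking is (distinct evidence types, total evidence, name, id) — a total
order, so reports are deterministic.

### Report

One `ReportModel` holds every rendered number; templates contain no
literals, so nothing can appear in the HTML that is absent from the model.
Sections not run render as explicit "not run" blocks.  The HTML is fully
self-contained (inline CSS/JS table sorting and filtering, no network
assets); every table is also written as CSV, and the whole model as JSON.
The print-ready summary replaces PDF typesetting: the clinical content, not
the typesetting, is the deliverable.  QC is pass-through only.

## Synthetic data generator

Default study conditions: 50 cohort samples (40 tumor / 10 normal — the
tumor-heavy imbalance of real reference cohorts, at desk scale), 5,000
genes of which 156 (fraction 0.0312) are background-silent, expressed-gene
means LogNormal(ln 100, 1), NB dispersion Uniform(0.05, 0.2) (moderate
biological dispersion), lognormal depth multipliers with log-SD 0.3.
Tumor-only class structure plants 10-gene mean-shift blocks per subtype and
for ER status.  The patient is drawn from the normal model with
multiplicative spikes at stated log2 fold changes.  Pathway topologies are
random connected DAGs (chain backbone plus forward edges) with an 80/20
activation/inhibition mix; the planted pathway puts coordinately up-spiked
genes upstream of a chain, producing a large positive `tA`.  Clinical
fixtures (toy VCF, annotation bundle, fusion and drug tables) are built so
every filter/join/match outcome is hand-enumerable.

What the generator does *not* emulate: gene-gene expression covariance,
GC/length biases, isoform structure, subclonal mixtures, batch effects, or
realistic pathway curation.  Passing tests therefore demonstrate that the
*algorithms* implement their contracts under the assumed NB model — not
that the pipeline's clinical calls are accurate on real tumors, which
depends on reference cohort quality and annotation databases.

All randomness flows through `numpy.random.default_rng` seeds; a fixed seed
reproduces every matrix, draw and report byte-for-byte.

## Problem sizes

Tests and the acceptance script use desk-scale sizes chosen to make the
statistical checks sharp but quick: 200 random matrices for the size-factor
oracle, the full 50-sample cohort for add-on consistency, 5,000 null +
50 spiked genes for DE calibration, 100 random datasets for the classifier
oracle, the 4-class design (500 genes, 30 shifted by 2 pooled SDs,
40/class) for held-out error, 100 random DAGs and 50 null pathways
(500 bootstrap draws) for the pathway engine, and one full CLI run on the
default fixture.

## Known limitations

- Dispersion from ≤10 normal samples is noisy; borderline calls (especially
  down-regulation) fluctuate between runs of the generator.
- The single-sample NB test treats frozen normal parameters as known; their
  estimation uncertainty is not propagated.
- The shrunken-centroid CV error is an in-cohort estimate; prospective
  accuracy requires an external validation cohort.
- Bootstrap `pPERT` resolution is bounded by 1/n_boot; very small combined
  p-values saturate accordingly.
- Annotation joins are exact-allele only; no normalization of complex
  indel representations is attempted.
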