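# nof1seq

**n-of-1 RNA-seq clinical reporting for breast cancer.**

`nof1seq` analyzes a *single* patient tumor RNA-seq sample against a frozen
reference cohort and produces a clinician-facing report: molecular
classification (ER/PR/HER2 receptor status and intrinsic subtype),
differentially expressed genes, dysregulated signaling pathways, filtered and
annotated variants, fusion candidates, and matched FDA-approved drugs.  It is
aimed at translational bioinformaticians who need a prospective, reproducible
single-sample pipeline: the reference cohort is summarized **once** into a
small "documentation by value" archive, and every later patient is processed
identically without touching the cohort again.

## The model

**Add-on normalization.** The cohort is reduced to per-gene geometric means
`g_j = exp(mean_i log c_ji)` (zero whenever any cohort count is zero).  A new
sample with counts `x_j` gets the median-of-ratios size factor

```
s = median_{j : g_j > 0, x_j > 0}  x_j / g_j
```

and log expression `log2(x_j / s + 1)`.  A sample that was part of the cohort
recovers its cohort size factor exactly.

**Reliability filter.** Genes silent in *every* cohort sample form the
background set; the 0.95 quantile of the patient's expression over those
genes is the noise ceiling, and only genes strictly above it are analyzed.

**Single-sample differential expression.** For each reliable gene the frozen
normal-tissue samples provide a mean `m_j` and a method-of-moments dispersion
`a_j` (variance `m + a m^2`).  The patient count is tested two-sided against
`NB(mean = m_j s, a_j)` by doubling the smaller tail; p-values are
Benjamini-Hochberg adjusted, and calls require adjusted p < 0.05 and
|log2 fold change| >= 1 (pseudocount 1).

**Classification.** Nearest-shrunken-centroid models: standardized centroid
deviations `d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0))` are soft-thresholded by a
shrinkage Δ chosen by stratified cross-validation; a profile is assigned to
`argmin_k Σ_j (x_j − x̄'_kj)² / (s_j + s0)² − 2 ln π_k`, with probabilities
∝ `exp(−δ_k/2)`.

**Pathway impact.** Fold changes propagate through signed pathway
topologies, `PF = (I − B)^{-1} ΔE` with `B_ij = β_ij / n_downstream(j)`; the
total net accumulation `tA = Σ(PF − ΔE)` is scored by a placement bootstrap
(`pPERT`), combined with hypergeometric over-representation (`pNDE`) as
`pG = c − c ln c`, `c = pNDE·pPERT`, and BH-adjusted over pathways.

**Clinical rules.** Variants are removed when flagged common or when their
population MAF exceeds 0.1 (absent MAF retains); annotations join only on an
exact (chrom, pos, ref, alt) allele match.  Approved drugs match
up-regulated targets through inhibitor/antagonist/antibody actions,
down-regulated targets through agonist actions, plus exact variant-drug
rules and significant pathway memberships, ranked by evidence breadth.

## Worked example

Everything runs from synthetic fixtures — no downloads:

```
$ nof1seq make-fixtures --out demo --seed 1
fixtures written to demo (25 up / 10 down spikes, planted pathway PW_PLANTED)

$ nof1seq build-ref --counts demo/cohort.tsv --metadata demo/samples.tsv \
      --label subtype --label er_status --out demo/ref.json --seed 1
trained classifier 'subtype': delta=4.370, CV error 0.000, 9 genes
trained classifier 'er_status': delta=3.763, CV error 0.000, 6 genes
frozen reference written to demo/ref.json: 5000 genes, 156 background genes

$ nof1seq analyze --counts demo/patient.tsv --reference demo/ref.json \
      --out demo/report --pathways demo/pathways.tsv --vcf demo/patient.vcf \
      --bundle demo/bundle --fusions demo/fusions.tsv --drugs demo/drugs.tsv --seed 1
profile: size factor 1.377, 4844 reliable genes, 84 DE genes
classifier er_status: negative (p=0.748)
classifier subtype: Basal (p=0.305)
pathways: 21 analyzed, 1 significant
variants: 6 called, 3 retained, 3 removed
drug matching: 2 candidate drugs
report written to demo/report/report.html
```

Reading the output: the patient sample was sequenced ~1.38x deeper than the
reference average; 4,844 genes clear the background noise ceiling; 84 genes
(including the planted spikes) are called differentially expressed; the
planted pathway is the one significant pathway; of the 6 toy variants the 3
population-common ones are filtered out; and the drug table links an
approved inhibitor to its up-regulated target, the retained variant in that
gene and the activated pathway.  `demo/report/` contains the interactive
`report.html`, a print-ready `summary.html`, one CSV per table and the full
`report_model.json`.

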