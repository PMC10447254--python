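# mtkit

Mitochondrial DNA heteroplasmy, copy number and control-region analysis for
population-scale whole-genome sequencing.

Blood WGS carries a quantitative readout of mitochondrial biology: the ratio
of mtDNA to nuclear coverage estimates mtDNA copy number (mtCN), allele
fractions at mtDNA sites quantify heteroplasmy, and the fine structure of
coverage across the non-coding region (NCR) tracks replication intermediates
(7S DNA, the nascent-strand "DNA flap", the RNA primer). All three are noisy:
nuclear insertions of mtDNA (NUMTs) masquerade as low-fraction heteroplasmy,
blood-cell composition and even the clock time of the blood draw confound
mtCN, and the circular genome breaks naive coordinate arithmetic at the
linearisation origin.

`mtkit` implements the computational core of a pipeline that addresses each
of these, plus the statistical machinery used downstream of genome-wide
association on the resulting traits. It is a library first and a small CLI
second, aimed at statistical geneticists working with biobank-style cohorts.

## What is implemented

* **Consensus self-reference liftover** (`mtkit.selfref`) — fold a sample's
  homoplasmic calls (allele fraction >= 0.95) into a per-sample consensus,
  then lift variant calls and per-base coverage back to reference
  coordinates, composing alleles through the applied edits; modular
  origin-shift arithmetic for circular-genome calling.
* **Coverage and mtCN** (`mtkit.coverage`) —
  `mean coverage = (mapped - singletons - discordant - duplicates) x read length / genome length`,
  and `mtCN = 2 x (mean or median mtDNA coverage) / (mean nuclear coverage)`.
* **Post-calling QC** (`mtkit.qc`) — sample filters (mtCN < 50,
  contamination > 2%, batch and overlap flags), variant filters (fractions
  < 0.01 recoded to reference, < 0.05 removed as NUMT risk, caller flags
  removed), site classification with a coverage-100 floor, and selection of
  common heteroplasmies (>= 0.1% of samples in (0, 0.5), >= 500 carriers).
* **Phenotype construction** (`mtkit.pheno`) — case-only and case-control
  heteroplasmy matrices with explicit missingness, sensitivity filters,
  rank-based inverse-normal transform, mutational spectrum counts.
* **Covariate adjustment** (`mtkit.adjust`) — natural-spline bases (5 df
  draw-time spline, seasonal-knot date spline), fasting/centre/month
  recodings, blood-index outlier masking at |Z| > 4, F-test-gated
  residualisation at alpha = 0.05/40 with log-scale handling for mtCN, plus
  carrier-phenotype t-tests (BH-corrected) and logistic disease models.
* **NCR coverage discrepancy** (`mtkit.ncr`) — region medians for 7S DNA /
  DNA flap / RNA primer and residual phenotypes with haplogroup
  interactions.
* **chrM:302 length heteroplasmy** (`mtkit.csb2`) — bulk composition over
  {reference, +C, +CC, +CCC, Other} and single-cell read classification with
  the anchored motif `AA(CCC+[CT]CC+)GC`, per-cell filtering (>= 20 reads)
  and count-pooled pseudo-bulk.
* **mtDNA population structure** (`mtkit.mtpop`) — binary homoplasmy
  genotype matrix (MAF >= 0.001), truncated-SVD PCA with projection of
  related samples, McFadden pseudo-R^2 for haplogroup prediction,
  heteroplasmy transmission pair tables.
* **Post-GWAS statistics** (`mtkit.assoc`) — CLPP colocalization
  (PIP_GWAS x PIP_eQTL), fine-mapping enrichment relative risks with
  bootstrap CIs, 2-Mb single-linkage locus definition and replication
  checks, NUMT-window LD screening, and inverse-variance-weighted vs Deming
  effect-size comparison.
* **Synthetic data** (`mtkit.simdata`) — cohorts, pedigrees, coverage and
  chrM:302 reads with the generative structure above, so every module is
  testable without restricted data.

## Worked example

```python
import numpy as np
import statsmodels.api as sm
from mtkit.coverage import AlignmentStats, mean_nuc_coverage, compute_mtcn
from mtkit.simdata import SimConfig, simulate_cohort
from mtkit.adjust import build_design, gated_adjust, rescale_adjusted

stats = AlignmentStats(total_mapped_reads=800_000_000, singletons=2_000_000,
                       discordant_mate_reads=4_000_000,
                       duplicates=60_000_000, read_length=151)
nuc = mean_nuc_coverage(stats)          # 38.55x
mtcn = compute_mtcn(1000.0, nuc)        # 51.88 copies per diploid genome

cohort = simulate_cohort(SimConfig(n_samples=5000, seed=1))
meta = cohort["metadata"]
X, mask = build_design(meta, model="joint")
adj, report = gated_adjust(meta["mtcn"], X, scale="log", row_mask=mask)
used = adj.notna()
mtcn_adj = rescale_adjusted(adj[used], np.log(meta["mtcn"][used]).mean(),
                            "exp_add_mean")
fit = sm.OLS(adj[used].to_numpy(),
             sm.add_constant(meta["age"][used].to_numpy())).fit()
```

Output for this run:

```
mean nuclear coverage: 38.55x
mtCN at mean mtDNA coverage 1000x: 51.88 copies
F = 59.3, p = 0, gated = True
mean mtCN_adj = 62.45 copies per diploid genome (n = 4998)
age slope on log mtCN_adj: -0.00190 per year (~1.9% decline per decade)
```

The joint technical+blood model clears the Bonferroni-corrected F-test, so
the trait is residualised; rescaling returns the adjusted copy number to an
absolute scale, and the regression on age recovers the cohort's planted
~2%-per-decade decline.

A `mtkit` console script exposes the main flows
(`mtkit sim`, `mtkit qc`, `mtkit adjust`, `mtkit selfref build|lift`,
`mtkit mtcn`, `mtkit csb2 bulk|cells`, `mtkit assoc loci|compare`); run any
of them with `--help`.

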