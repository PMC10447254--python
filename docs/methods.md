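# Methods

This note documents the models, conventions and numerical choices behind
`mtkit`, and what the synthetic-data generator does and does not emulate.

## Consensus self-reference and liftover

Variant calling against a fixed reference is biased near common
homoplasmies: reads carrying a sample's own major allele mismatch the
reference and are penalised in alignment and calling. The self-reference
approach folds all homoplasmic PASS calls (allele fraction >= a threshold,
default 0.95) into a per-sample consensus, calls variants against it, and
lifts everything back.

Conventions:

* Variant positions are 1-based inclusive (VCF); alignment blocks are
  0-based half-open internally. Indels are left-aligned with the VCF anchor
  base.
* Overlapping homoplasmic calls are applied first-in-position-order; later
  overlaps are skipped and reported with reason `overlap`. This is a
  deterministic stand-in for whatever conflict policy an upstream caller
  would impose, and is visible in the `skipped` output rather than silent.
* Inserted consensus bases map to the left flanking reference base
  (left-anchor rule); reference bases deleted in the consensus lift to
  nothing (`to_consensus` returns none) and inherit the left consensus
  anchor's value when coverage is lifted. Inserted bases contribute no
  coverage to the reference axis.
* Call liftover composes alleles through the applied edits by replaying a
  local window as three haplotypes: the reference segment, the consensus
  segment, and the consensus segment with the new call applied. If applying
  the call restores the reference segment exactly, the sample's
  reference-relative variant is the folded homoplasmy itself, carried by the
  complement `1 - f` of the molecules; otherwise the call-applied segment is
  emitted at fraction `f`. Alleles are then trimmed (shared suffix, then
  prefix) to minimal VCF form. Compositions that cannot be represented are
  returned in a rejects list with a reason, never dropped.
* Control-region calling on a circular genome uses an origin-shifted copy of
  the molecule; `shift_coordinate` maps `shifted pos 1 -> original pos
  shift+1` modulo the genome length. The default shift is 8,000 bases
  (roughly half the 16,569-base genome, the usual mitochondria-mode
  convention).

## Coverage and mtDNA copy number

Nuclear coverage is estimated from alignment flag statistics —
`(mapped - singletons - discordant-mate reads - duplicates) x read length /
genome length` — rather than a pileup; the read counts are intended to be
computed over autosomes, and the default `genome_length` is the GRCh38
autosome span. mtCN is `2 x mtDNA coverage / nuclear coverage`, using mean
mtDNA coverage by default with a median option. The formula is homogeneous:
scaling both coverages leaves mtCN unchanged, which the tests exploit.

## Post-calling QC

Sample level: mtCN < 50 (below which heteroplasmic SNV counts inflate,
consistent with NUMT contamination), contamination > 2% on either the mtDNA
or nuclear estimate, low-allele-fraction haplogroup patterns, cross-sample
homoplasmy overlap, and excluded processing batches. An optional upper bound
(mtCN > 350) is off by default. Variant level: fractions below 0.01 are
recoded to reference (heteroplasmy 0), fractions in [0.01, 0.05) are removed
as NUMT-artefact risk, flagged calls are removed. Ties follow the stated
inequalities: exactly 0.05 is kept, exactly 0.01 is not floored. Site status
uses a minimum coverage of 100 to separate confident reference from missing.

Removed calls are retained in an audit table with reasons, because the
chrM:302 composition needs the QC-fail heteroplasmy mass.

## Phenotypes

Case-only traits carry the allele fraction among carriers only;
homoplasmic-alternative samples are always missing (they are a different
biological state, not a high heteroplasmy). Case-control traits code
detectable heteroplasmy as 1 and *confident* reference as 0 — coverage >=
100 at the site and no QC-failed call there — leaving everything else
missing, so controls are not contaminated by dropout. The inverse-normal
transform uses offset 0.5 (`Phi^-1((rank - 0.5)/n)`) with average ranks on
ties; the offset is a documented flag since alternatives (Blom 3/8) exist.
Mutational spectra pool transitions and subclass transversions by unordered
reference-strand base pair, with explicit zero rows so cohort means are over
all individuals.

## Covariate adjustment

The technical model is
`ns(draw time, 5) + centre + fasting-hour indicators + ns(assessment date,
seasonal knots) + month indicators`; the blood model adds 14 non-redundant
cell-count/volume indices; the joint model contains both. Seasonal knots sit
on a 3-month grid from 2007-07-01 to 2010-07-01. Fasting 0 is recoded to 1
and values above 18 h to 18. Blood measurements at |Z| > 4 mask the row for
that model (deletion, not imputation). The natural-spline basis is the
standard truncated-power construction (linear beyond the boundary knots);
boundary knots sit at the data range for df-specified bases and at the first
and last supplied knots otherwise — the tests verify span-equivalence
against an independent cubic-regression-spline implementation.

Residualisation is gated per trait by the joint-model F-test at
alpha = 0.05/40 (the 39 common heteroplasmies plus mtCN); unmatched traits
pass through unchanged. mtCN is adjusted as log(mtCN) and re-exponentiated
after adding the pre-adjustment log-mean for display. Design columns are
standardised internally before the least-squares fit — the residuals are
mathematically unchanged but the orthogonality of residuals to design
columns then holds to ~1e-14 in correlation, comfortably inside the 1e-10
contract.

Carrier-phenotype comparisons residualise on
`age + sex + age^2 + age^2 x sex + age x sex + ancestry`, log-transforming
log-normal biomarkers and averaging left/right paired measures first; a
two-sample t-test runs only when carriers contribute more than ten defined
values, with Benjamini-Hochberg q-values across the tested set. Disease
models are logistic with the same demographic terms, haplogroup indicators
restricted to haplogroups of >= 30 members for mtDNA-derived traits, and
OR = exp(beta) with a Wald 95% CI; perfect separation is flagged, not
estimated.

## NCR coverage-discrepancy traits

The three regions default to rCRS-style approximations: the first third of
the 7S DNA span (16106 wrapping the origin), the DNA flap between the
heavy-strand origin (191) and CSBII (299), and the RNA primer between CSBIII
(363) and the LSP (392). These end-points are conventional annotations, not
measured quantities, and are overridable. The trait is the residual of flap
coverage on predictor coverage with haplogroup indicators, predictor x
haplogroup interactions and optional blood/technical covariates; haplogroups
under 30 members are excluded. Wrap-around intervals use circular indexing.

## chrM:302 length heteroplasmy

Bulk composition treats the reference fraction as one minus the summed
allele mass (QC-pass named alleles +C/+CC/+CCC, everything else plus the
summed QC-fail mass in Other); named alleles below 0.05 move to Other,
missing named alleles are zero, and samples with post-realignment depth
under 100 are excluded. Every emitted profile sums to 1 within 1e-9 by
construction.

Read classification anchors the motif `AA(CCC+[CT]CC+)GC` on the constant
bases flanking the two poly-C tracts; the first match wins. An interrupted
capture (containing T) yields tract lengths `G{m}AG{n}`; a pure-C capture is
kept as a distinct uninterrupted class labelled by total length, since the
tract split is undefined for it — uninterrupted alleles are excluded from
the top-three set by default. Reads must be supplied on the sequenced strand
(reverse-strand reads reverse-complemented upstream). Cells need >= 20
classified reads; pseudo-bulk pools counts across retained cells before
normalising, which is not the mean of per-cell fractions.

## Population structure and transmission

The genotype matrix codes QC-pass homoplasmies as 1 at cohort MAF >= 0.001.
PCA centres and scales columns (column standard deviation after centring —
the binary-variant alternative p(1-p) scaling gives the same span), takes a
truncated SVD over unrelated samples and projects related samples through
the loadings; PC signs are fixed by making each component's
largest-magnitude loading positive. A dense matrix SVD is used — cohort
matrices at this scale do not need an implicitly restarted solver. The
haplogroup model is a multinomial logistic fit (effectively unpenalised;
a ~1e-8 ridge for stability) with McFadden's
`1 - loglik / null loglik` against an intercept-only null; classes under 30
samples are excluded and near-perfect separation is flagged.

Transmission tables keep variants found in >= 5 samples and emit one row per
(variant, pair) with both members' fractions; a non-carrying partner is 0
only when confidently reference, missing otherwise. The quantitative
transmission correlation is computed among pairs where both members carry
the variant: transmitted mixtures then show high correlation, while
coincidental co-occurrence of independent somatic variants shows none —
summarising with rows where one member is structurally zero would instead
measure the carrier/non-carrier mixture, not transmission.

## Post-GWAS statistics

CLPP is the PIP product, bounded by the smaller PIP. Enrichment is the
relative risk of an annotation between well fine-mapped (PIP > 0.1) and
poorly fine-mapped (PIP <= 0.01) variants, with 95% percentile-bootstrap CIs
(5,000 replicates by default) resampling variants independently within the
two strata; a zero denominator leaves the RR undefined and flagged. Loci are
single-linkage merges of lead SNPs within 2 Mb per chromosome (idempotent
and order-invariant); replication classifies the best p within 2 Mb of a
previous locus at 5e-5 / 5e-8. NUMT screening pads intervals by 500 bases,
merges overlaps, adds 10 kb flanks and flags leads with r^2 > 0.1 to any
window SNP, marking LD-lookup failures unevaluable. Effect comparison
offers inverse-variance-weighted least squares (product weights
`1/(se_x^2 se_y^2)`; attenuated under noise in x) and Deming
errors-in-variables regression with variance ratio
`lambda = mean(se_y^2)/mean(se_x^2)` and a leave-one-out jackknife standard
error — the cross-cohort convention, with alleles oriented so the reference
cohort's effects are positive.

## Synthetic data: what it emulates and what it does not

The generator draws ages uniformly on 40-70, assessment dates on the
2007-2010 window, and builds log mtCN around a base of 61.66 copies with a
-0.002/yr age slope (about 2% per decade), a 0.05-amplitude sinusoid in
draw time, a 0.05-amplitude seasonal sinusoid, slopes on the first three
blood indices (0.10, -0.05, 0.03) and residual s.d. 0.15. The first blood
index carries a deliberate age loading (0.01) so that the raw age slope is
confounded while the adjusted one is not: the loading was chosen by a power
calculation so the raw bias is ~8 standard errors at n = 20,000 while the
attenuation induced in the adjusted slope (the design absorbs a fraction
`c^2 var(age) / (c^2 var(age) + 1)` of the age signal through that index) is
~0.1 standard errors.

Heteroplasmy combines three processes: inherited indel mixtures at five
control-region length-variant sites with Beta(2, 8) maternal founder
fractions (low-fraction-skewed) transmitted with truncated-Gaussian jitter
(s.d. 0.05); somatic SNVs whose expected count rises with age; and
NUMT-artefact calls uniform on (0.01, 0.049), i.e. inside the QC removal
band by construction. Pedigrees transmit indels maternally only — fathers
carry indels at father-lineage sites disjoint from the child's maternal
sites, making paternal sharing structurally zero — and somatic SNVs arise
independently at recurrent hotspot sites so the five-carrier filter retains
them while pair members' fractions stay independent.

Not emulated: realistic read-level error profiles outside the chrM:300-318
window, haplogroup-correlated variant content (haplogroups are labels, not
sequences), genuine NUMT alignment artefacts (only their low-fraction call
signature), relatedness beyond the explicit pairs, and ascertainment or
missingness patterns of real biobanks. Passing tests therefore demonstrate
that the estimators recover the stated generative structure at the stated
sizes, not that they are robust to every pathology of real sequencing data.

## Problem sizes and seeds

The test and acceptance runs use: 1,000 random 200-bp circular references
for liftover fuzzing; all 16,569 positions for shift arithmetic; 100 fuzzed
alignment summaries; 10,000 reads for the classifier oracle and 1e5 reads
for mixture recovery; 10,000 fuzzed composition call sets; n = 20,000 for
adjustment recovery; 500 trios for transmission; 800 samples for the
coverage-discrepancy trait; 1,000 random lead sets, 200 simulated enrichment
datasets (1,000 bootstrap replicates each) and 100 errors-in-variables
replicates at n = 500 for the post-GWAS checks. All randomness is seeded;
the acceptance script derives every stream from its `--seed` argument.
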