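# Methods

## Scope and model

The package implements one analysis idea end to end: use the enrichment of
a PARP-inhibitor (PARPi) response gene signature in biomarker-defined
tumour subsets as a *surrogate* for PARPi response, and then ask whether
cheaper or more accessible biomarkers (microsatellite instability status,
TP53 mutation status, PARP1/PARP2 expression, fraction genome altered,
aneuploidy) track that surrogate as well as the homologous-recombination-
deficiency scar score LST does. Two comparative statistics make the
"as well as" precise: a Fisher-z difference test on enrichment scores and
a paired Wilcoxon test on gene-module overlap fractions (GSEF).

## Coordinates and segment model

All genomic coordinates are 1-based and inclusive (SEG convention);
interval length is `end − start + 1`. A segment carries a log2 copy ratio
and optionally integer allele-specific (major, minor) copy numbers. The
two representations serve different scores: FGA and the aneuploidy score
read the log2 ratio; TAI and LOH need the allele-specific fields; LST and
smoothing compare "copy states", which are the (major, minor) pair when
present and otherwise the log2 ratio quantized at a tolerance of 0.1.
Without allele-specific data TAI and LOH — and therefore HRD — are
undefined and reported as missing, which mirrors what happens to real
cohorts lacking ASCAT calls.

The packaged hg19 table (UCSC chromosome lengths and acen boundaries)
defines arms; the centromere interval belongs to neither arm.

## Scar scores

* **Smoothing** (used inside LST): segments shorter than 3 Mb are removed,
  smallest first, and the flanking segments merged when their copy states
  agree; adjacent equal-state segments are also merged. Iterated to a
  fixed point. Merged log2 ratios are length-weighted means.
* **LST** counts junctions, per chromosome arm after smoothing, where both
  flanking segments span ≥ 10 Mb and differ in state. Segments are clipped
  to arms first, so a transition across the centromere gap never counts.
* **TAI** counts maximal allelic-imbalance runs (major ≠ minor) that
  include the first or last assayed segment of their chromosome, do not
  cross the centromere, and span ≥ 11 Mb.
* **LOH** counts runs with minor = 0 and major ≥ 1 longer than 15 Mb,
  excluding runs that cover every assayed segment of a chromosome
  (whole-chromosome LOH carries no HRD information).
* **HRD** = LST + TAI + LOH, only when all three exist.
* **FGA** = altered length / assayed length with |log2| > 0.2 (strict),
  cBioPortal-style; unassayed chromosomes drop out of both numerator and
  denominator.
* **Aneuploidy** counts arms in which gained or lost length (one
  direction) covers ≥ 50% of the assayed arm; scope is the standard 39
  autosomal arms (sex chromosomes and acrocentric p arms excluded).

The length cutoffs (3/10/11/15 Mb, 0.2, 50%) are the conventional
parameterizations of these scores and are all keyword-configurable.
Continuous scores become GSEA phenotypes through `dichotomize_score`
(default LST cut 15, `high_is="ge"`) or `median_split` (ties to "low");
a split with an empty class is flagged degenerate and refused by the
phenotype-permutation machinery.

## Expression handling

Per-cohort normalization is the two-step fractional-rank transform:
average-tie fractional ranks per gene, then normal quantiles via
Φ⁻¹(rank/(n+1)). The offset in the denominator is the classical
rank/(n+1) choice; since every downstream statistic is rank-based within
genes, the choice affects only the metric's scale, not any ordering.
Missing expression values are rejected at ingestion (imputation is out of
scope). GCT v1.2 and two-class categorical CLS files are written
bit-exactly round-trippable (floats serialized with `repr`, parsed with
pandas' round-trip parser).

Consensus-molecular-subtype labels recode as CMS1 → MSI/Hypermutated,
CMS2/CMS3 → MSS/Epithelial-CIN, CMS4 → MSS/Mesenchymal. Assigning CMS3
(metabolic) to the epithelial/CIN tier is the package's choice — the
two-tier MSI/MSS side of the mapping is standard, but three-tier schemes
vary; the mapping is a single table (`expression._CMS_MAP`) if a project
needs a different convention.

## GSEA core

Genes are ranked by signal-to-noise, s2n = (μ_A − μ_B)/(σ_A + σ_B), with
each class σ floored at max(0.2·|μ|, 0.2) — the floor of the reference
implementation, which stops near-constant genes from dominating. Ties
break lexicographically by gene id so runs are deterministic.

The enrichment score is the signed maximum deviation of the running sum
that gains |metric|^p (normalized over set members, p = 1 by default) at
hits and loses 1/(N − N_H) at misses. The leading edge is the set members
at or before the extremum (after, for negative ES). Significance comes
from n_perm = 1000 permutations by default: either sample relabelings
("phenotype", unstratified) or random equal-size member sets
("gene_set"). The nominal p is the add-one fraction of same-signed null
scores at least as extreme, reported as "<0.001" when it hits the
1/(n_perm+1) floor; NES divides ES by the mean magnitude of same-signed
null scores. With a single gene set per run the FDR q value equals the
nominal p, which is why those two columns agree in single-set reports.

Numerical notes: permutations are scored in vectorized blocks of 256; the
running-sum extremum takes the first index at the maximum |deviation|. An
exact tie between the largest positive and largest negative deviation is
resolved by floating-point rounding; the test suite treats the sign as a
convention in that measure-zero case. ES values of exactly ±1 (perfect
separation) are legal GSEA outputs but have no finite Fisher transform;
the pipeline records such pairs as per-pair failures instead of aborting.

## Comparative statistics

The differential-ES test treats ES like a correlation coefficient:
z = (atanh ES₁ − atanh ES₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided
normal p, where each n is the number of classifiable samples for that
biomarker. P values are Benjamini–Hochberg adjusted over the family of
reference-vs-other pairs in one run. BH is the standard step-up
(statsmodels); note it is *not* idempotent, only monotone and dominating.

GSEF compares two biomarkers' enriched-gene lists across a panel of drug
gene modules: per module the fraction of members present in each list,
then a Wilcoxon signed-rank test on the paired differences. Zero
differences are dropped (Wilcoxon's rule; Pratt handling available). Up
to 25 informative pairs the null distribution is enumerated exactly by a
dynamic program over sign assignments (midranks doubled to integers);
above that a normal approximation with tie and continuity corrections is
used. At the typical panel size of 22 modules the two paths agree within
0.01 in p. An all-zero difference vector yields a degenerate-flagged
result with p = 1 rather than an error.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not tumour biology:

* **Expression**: i.i.d. standard-normal baseline, with a planted gene
  set mean-shifted by `enrichment_shift` SD in the positive class.
  Heavier-tailed noise is deliberately omitted — the fractional-rank
  transform would erase it anyway.
* **Biomarkers**: each sample copies its enrichment-class label with
  probability `association`, otherwise draws an independent Bernoulli
  label. One parameter thus controls how well a biomarker "predicts" the
  planted response.
* **Segments** (autosomes only): each planted event occupies its own arm
  with geometry chosen so it satisfies exactly one scoring rule — a
  two-segment arm with both flanks ≥ 10 Mb for LST, a whole-arm
  major 2/minor 1 imbalance for TAI, an interstitial copy-neutral
  major 2/minor 0 region with short (< 10 Mb) heterozygous flanks for
  LOH — and short (< 10 Mb) gain segments on the remaining arms tune FGA
  to its target without creating any large-scale transition. Feasibility
  is checked (an arm too short, or an FGA target below the alterations
  the planted events already imply, raises with the reason), and every
  profile's ground truth is returned alongside.

What passing tests on these cohorts shows: the scorers implement their
rules exactly, the permutation test is calibrated and recovers planted
signals, and the comparative statistics distinguish unequal biomarkers
while not flagging equal ones. What it does not show: robustness to
segmentation noise, purity/ploidy distortion, correlated genes, or
breakpoint clustering — none of which the generator attempts.

## Study conditions used in tests and the acceptance script

Cohorts are 120 samples (60/60), 1000 genes, a 50-gene planted set.
Calibration uses 200 null replicates at 99 permutations (rejection rate
at α = 0.05 checked against the central 95% binomial band); recovery uses
20 replicates at shift 1 SD and 1000 permutations. The end-to-end
equal/unequal-signal comparisons run at shift 0.4 with biomarker
association 0.9: at that shift the planted ES sits near 0.8, the moderate
range where the Fisher-z comparison is meaningful, whereas shifts ≥ 0.75
saturate ES near 1, where atanh amplifies label-noise jitter and perfect
separation (ES = 1) has no z at all. Scar honesty uses 100 profiles with
planted counts up to (8, 4, 4) and FGA targets in [0.15, 0.55]; with the
filler geometry (9.5 Mb gains, 3 Mb spacers) targets up to about 0.6 are
feasible, and achieved FGA lands within 0.001 of target in practice
(0.02 tolerated).

## Known limitations

* LST requires a smoothing convention the literature states informally;
  other implementations differ in how they merge across removed segments
  and in the log2-equality tolerance. Both knobs are exposed.
* TAI's "reaches a telomere" is implemented as "includes the first or
  last assayed segment of the chromosome", which on sparsely assayed
  profiles may differ from a coordinate-based telomere rule.
* The differential-ES test inherits the independence and normal-theory
  assumptions of the classical two-correlation comparison; overlapping
  sample sets between biomarkers violate independence, and the test is
  then anticonservative.
* Multi-gene-set FDR across a collection is not implemented: runs score
  one compiled set per phenotype, where FDR q = nominal p.
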