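# Methods

## Study design the package models

A case–control somatic-mutation study: tumor tissue (two subtypes, BCC and
SCC) and matched blood from each case, plus non-lesional healthy skin and
matched blood from an *independent* set of control patients. Somatic calls
are tissue calls absent from the same patient's blood. Arsenic exposure is
measured per patient as the urinary arsenic–creatinine ratio (UACR, µg/g)
and dichotomized at the population median, 192 µg/g: low = UACR ≤ 192,
high = UACR > 192. Expression is 3′-tag RNA-seq from the same tissue
samples, processed as counts per million (CPM) and log2(CPM + 1).

## Coordinate conventions and deletion identity

All coordinates are 1-based inclusive; a pure deletion stores the deleted
bases as its reference allele and `-` as its alternate allele. VCF input is
normalized on import (anchor base stripped), so both input dialects yield
identical identities. A deletion's identity — the `DelKey` — is
(chromosome, start, end, deleted sequence); deletions at the same start but
of different lengths are distinct coordinates. Germline subtraction matches
on exact identity, not positional overlap: partial-overlap semantics are
deliberately not defined, since the unit of analysis downstream is the
unique coordinate.

QC thresholds (coverage ≥ 10, supporting reads ≥ 2, frequency ≥ 2%,
quality ≥ Q60) are all inclusive lower bounds. Public-database germline
filtering is supported only as a user-supplied exclusion list of identity
keys; no database is bundled. An optional target-region mask drops
off-target calls.

## Homopolymer context

A deletion is homopolymeric when its deleted bases are all one base B and
the maximal run of B in the *reference* (pre-deletion) sequence containing
the deleted span has length ≥ `min_run`. The default `min_run` is 3 — the
shortest tract length at which such deletions are observed in practice; it
is configurable because it is a convention, not an estimate. Mixed-base
deletions are never homopolymeric, even when flanked by a tract of another
base, and carry no run length (`run_length = None`); tallies therefore
count them only in the denominators. Runs are measured by scanning outward
from the span, which a brute-force windowed count verifies at every
position of a random 10 kb sequence in the test suite.

## Gene-set ANOVA

For one gene set and one target gene, the model over all (sample, gene)
observations is an ordinary least-squares fit with treatment coding and a
single pooled error variance:

    Y = μ + T + G + T×G + T×Mut + ε            (base model)
    Y = μ + T + G + T×G + T×Mut + T×As + T×Mut×As + ε   (exposure model)

* `T` — tissue, 0 healthy skin / 1 tumor.
* `G` — gene factor (reference level: alphabetically first gene).
* `Mut` — patient carries ≥ 1 subtype-associated deletion of the target
  gene. Controls are independent patients with no tumor, so `Mut = 0` for
  every healthy sample; a `Mut` main effect would be perfectly aliased with
  `T×Mut` and is not included.
* `As` — exposure stratum. Controls are assigned a stratum from their own
  UACR so each subgroup has matched reference tissue, but `As` likewise
  enters only through interactions with `T`: the healthy reference mean is
  shared across strata. (A pooled-control variant would behave identically
  here for the same reason.)

Aliased design columns are removed by a greedy left-to-right rank check
(tolerance 1e-8 relative), so lower-order terms always survive their
aliases; with a single gene the model collapses to intercept + tissue and
the tissue contrast reproduces the pooled two-sample t-test exactly.
Factor levels absent from the data (e.g. no carriers) drop out of the
design; a missing *combination* of present levels is an error naming the
stratum.

The stratum fold change for (Mut = m, As = a) is the tumor-minus-healthy
difference in mean log2 CPM, averaged with equal weight over the set's
genes (an estimated marginal contrast); its 95% CI uses the t distribution
on the OLS residual df. Signed conversion: FC(d) = 2^d for d ≥ 0 and
−2^(−d) for d < 0, applied to the estimate and both CI bounds, so
down-regulation reads as a negative ratio and intervals straddling d = 0
read like "(−1.20 to 1.12)". Interaction tests are extra-sum-of-squares
F-tests of the term's columns against the model without them; the reported
"interaction p" is `T×Mut` in the base model and `T×Mut×As` in the exposure
model (the minimal term whose test distinguishes the four subgroup shifts).
Bonferroni correction multiplies by the number of gene sets screened.

Variance is pooled across genes (one ε), matching the single-error model;
per-gene variance weighting, mixed effects and competitive (permutation)
gene-set tests are out of scope.

## Co-occurrence testing

Patient-level 2×2 cross-tabulations are tested with the two-sided Fisher
exact test under the probability-ordering definition: sum the
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (relative slack 1e-7 for
floating-point ties). Terms are computed in log space. With the observed
carrier counts (12, 2 / 4, 8 in 26 patients) this gives p = 0.0138 and an
odds ratio of 12; a Pearson chi-square without continuity correction is
provided as an alternative and rounds to the same two decimals on that
table. The implementation is verified against full enumeration for all
tables with total ≤ 30 and against an independent library routine.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: 26 BCC + 6 SCC
cases and 16 healthy-skin controls, each with a matched blood sample; UACR
log-normal with median fixed at 192 µg/g (σ of ln UACR = 1.0, a realistic
spread for an exposed cohort) so the threshold is the population median by
construction; 65% of deletion coordinates in homopolymer tracts (run
lengths uniform on 3–25); target-gene (APC) carrier fraction 10/26; a
co-occurring SNV status drawn with P(SNV | carrier) = 0.8 vs 0.25;
per-patient somatic deletion counts Poisson (mean 25 tumor, 12 healthy)
drawn from tumor-only / shared / healthy-only coordinate pools, scaled down
from panel-scale totals to keep desk-scale runtimes. A configurable 5% of
somatic calls are sabotaged to fail exactly one QC threshold, exercising
rejection paths.

Design guarantees worth knowing:

* **Germline closure.** Blood tables contain exactly the planted germline
  SNVs, so subtraction removes exactly those calls.
* **Carrier recoverability.** Target-gene coordinates live in a reserved
  tumor-only pool sampled only by planted carriers (and carrier-defining
  calls always pass QC), so the observed carrier matrix equals the planted
  truth. Stratum occupancy is retried (or set verbatim via
  `stratum_counts`) so all four (carrier × exposure) subgroups are
  populated.
* **Exact expression truth on the CPM scale.** CPM is compositional: a
  one-sided gain in set-gene mass would deflate every gene's CPM and bias
  all contrasts downward. The generator pins each sample's total intensity
  to a common target by rescaling the ~200 background genes, so the planted
  stratum log2 shifts are exact on the CPM scale up to the log2(CPM + 1)
  pseudocount distortion (< ~0.02 log2 units at the simulated baselines of
  2^7–2^11 CPM-equivalents).

What the generator does **not** emulate: mutational signatures, read-level
noise (no FASTQ/BAM), overdispersed counts (counts are rounded scaled
intensities, not negative binomial), batch effects, gene–gene expression
correlation, and germline indels. Passing tests therefore demonstrate
correctness of the set algebra, annotation and estimators under the stated
model, not robustness to those real-data features.

## Calibration results the tests compute

* Stratum fold-change recovery: generating with true FCs (1.3, 2.33, 3.91,
  5.62) at n = 40/stratum, σ = 1, 20 genes — the estimator's own 95% CIs
  cover the truth in ≥ 90% of 200 replicates and the mean log2 bias per
  stratum stays below 0.02.
* Type-I error: under an equal-shift null, the `T×Mut×As` F-test rejects at
  α = 0.05 with empirical rate within [0.035, 0.065] over 2000 replicates
  (4 genes, n = 10/stratum — the test is exact under the model, so small
  cells suffice).
* Algebra: OLS coefficients match a direct normal-equations solve to 1e-8
  relative tolerance on random instances with ≤ 6 genes and ≤ 12 samples.

The simulation sizes above (replicate counts, genes per set, samples per
stratum) are the package's chosen desk-scale defaults; they were picked so
each property is tested at tight Monte-Carlo error while the whole suite
runs in well under a minute.

## Known limitations

* Germline subtraction is identity-exact; a re-aligned or left-shifted
  representation of the same indel would not match (inputs are normalized
  on import to mitigate this).
* The carrier matrix treats a gene as mutated regardless of how many
  distinct deletions support it; allele burden is not modeled.
* Healthy controls contribute to every stratum's reference mean; with very
  unbalanced exposure strata the shared-reference assumption matters and a
  stratified sensitivity fit is advisable.
* The Fisher test's probability-ordering definition is one of several
  two-sided conventions; the chi-square alternative is provided because the
  convention behind any individual published p-value may differ.
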