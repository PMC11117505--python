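# Methods

## Model and procedure

`fasdvar` analyses a small diploid cohort (by default 23 individuals,
6 FAS / 12 pFAS / 5 ARND) genotyped at candidate-gene variants, against a
reference population summarised as per-allele frequencies with a total
allele number (AN; default 5008 chromosomes, the size of 1000 Genomes
phase 3).  The pipeline is:

1. **Candidate subsetting.**  Variants are kept when their annotated gene
   belongs to the candidate panel (four panels; a gene may appear in
   several).
2. **Cohort frequencies.**  For each variant the tested-allele count is
   summed over non-missing genotypes; the allele number is 2 × non-missing
   samples.  Missing genotypes reduce AN rather than being imputed.
   Frequencies are kept as exact rationals and rounded only at output.
   The tested allele is taken from the reference table's `tested_allele`
   column — it may be the VCF REF allele (dosage is recoded 2 − d), since
   published risk alleles are oriented biologically, not by VCF ALT status.
3. **MAF filter + whitelist.**  A variant is testable when the reference
   minor-allele frequency is at least the smallest frequency observable in
   the cohort, 1/(2N) (= 1/46 ≈ 2.17% at N = 23), or when it is on a
   curated whitelist of literature-known rare variants; whitelisted
   variants also count toward the BH total.
4. **Chi-squared test.**  Pearson's statistic on the 2×2 allele-count
   table, 1 df, no continuity correction by default.  Reference counts are
   reconstructed from the published frequency by rounding half away from
   zero.  A zero column margin (allele absent or fixed in both groups)
   yields statistic 0, p 1.  A `use_yates` flag is provided; it is off by
   default because reconstructing published cohort-vs-reference results
   (e.g. cohort 0.96 vs reference 0.82 on 46 vs 5008 chromosomes,
   p ≈ 1.6 × 10⁻²) matches the uncorrected statistic.
5. **Benjamini–Hochberg.**  Step-up at α = 0.05 with an optional fixed
   total test count n (`n_tests_override`) that must be at least the
   number of p-values supplied; the reported threshold is k·α/n for the
   largest admissible rank k, or 0 when nothing is rejected.  Ties are
   handled naturally by the step-up rule.
6. **Risk/resilience classification.**  Damaging evidence is: SIFT
   "deleterious"; PolyPhen2 "possibly_damaging"/"probably_damaging"; CADD
   phred strictly greater than 10; or a non-"none" curated literature flag.
   With at least one line of evidence, enriched variants are called *risk*
   and depleted variants *resilience*; the annotated allele role
   (risk vs protective allele) changes the rationale wording — a depleted
   protective allele is reported as loss of protection — but not the call
   direction.  Without evidence the variant stays `candidate_only`.  The
   literature step is deliberately explicit input data (two annotation
   columns) rather than hidden judgment.
7. **Diagnosis partition and inclusion rules.**  A variant "occurs in" a
   diagnostic group when at least one member carries at least one tested
   allele.  Significant variants split into five disjoint sets: unique to
   FAS / pFAS / ARND, common to FAS and pFAS, common to all three.
   Patterns not named by that scheme (FAS+ARND, pFAS+ARND) are reported
   under the respective unique set but never seed the common-gene
   expansion, which operationalizes only the FAS–pFAS axis (the two
   diagnoses sharing sentinel facial features).  The rules run in order:
   (1) expand from FAS∕pFAS-common variants to all significant variants in
   those genes; (2) drop variants common to all three groups; (3) drop
   variants in genes with no pathway membership.
8. **Pathway burden matrix.**  For each person and each of the eight
   pathways (RA, SHH, WNT, FGF, TGF-β, RAS-MAPK, RHO-RAC, mTOR, fixed
   order), the entry is the summed tested-allele dosage of included
   risk-called variants in that pathway's genes (het = 1, hom = 2; missing
   counts 0).  "Risk alleles per person" is read as allele dosage, not
   carrier status.  A gene in several pathways contributes to each.
   Resilience-called variants are excluded by default (it is a risk-allele
   score); a flag includes them with weight −1 for exploration.
   Candidate-only variants never contribute.  Full provenance — every
   (sample, variant, gene, pathway, dosage) contribution — is retained and
   each matrix entry equals the sum of its provenance dosages.
9. **PCA and separation.**  PCA is an SVD of the centered (and by default
   unit-variance-scaled, ddof = 1) burden matrix; zero-variance columns are
   dropped with a warning when scaling; component signs are fixed by making
   each component's largest-magnitude loading positive; an all-identical
   matrix yields an explicitly degenerate result.  Group separation is the
   mean silhouette of diagnosis labels on PC1–PC2 plus an add-one
   permutation p-value under label shuffling.  The statistic exists because
   a visual "clusters by diagnosis" judgement is untestable; the PC1/PC2
   scatter (colored by diagnosis, shaped by ancestry label) is still
   emitted so the same contrast can be read off a plot, and ancestry labels
   are carried through so diagnosis- and ancestry-separation can be
   computed on the same scores.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | BH significance level |
| `n_tests_override` | none | fixed BH total test count (must be ≥ p-values supplied) |
| `use_yates` | off | continuity correction for the 2×2 test |
| `maf_threshold` | 1/(2N) | reference MAF floor; auto-derived from cohort size |
| `ref_an_default` | 5008 | reference allele number when a row lacks one |
| CADD cutoff | 10 (strict) | damaging-evidence threshold on CADD phred |
| PCA `center`/`scale` | on/on | pathway burdens are on different scales |

## Synthetic data

The generator emulates the study conditions the pipeline assumes: 23
individuals split 6/12/5 across FAS/pFAS/ARND, reference frequencies drawn
U(0.05, 0.95) (overridable per variant, e.g. 0.025 for rare literature-like
alleles), reference AN 5008, ~10/13 European/Indigenous ancestry labels.
Genotypes are Hardy–Weinberg draws, dosage ~ Binomial(2, p′), where the
cohort frequency solves logit p′ = logit p_ref + ln OR for a planted
per-variant odds ratio (OR = 1 is the null).  Per-(diagnosis, pathway)
burden planting adds Bernoulli risk alleles (probability δ divided by the
number of pathway variants, capped at dosage 2) to members of that
diagnosis, so the partition/inclusion/scoring stages see a real group
difference.  Planted variants are annotated damaging (deleterious SIFT,
CADD in (10.5, 35)); planted protective (OR < 1) variants get the
alcohol-protective literature flag and protective allele role.  Genes carry
two variants each; gene *i* is tagged with pathway *i* mod 8, every tenth
gene is pathway-less (so rule 3 is always exercised); panel ids cycle 1–4.

What the generator does **not** emulate: linkage disequilibrium between
variants (the statistics tested are per-variant), relatedness (the emulated
cohort contains sibling pairs, which violate allele-count independence; the
generator draws individuals independently), population structure beyond an
ancestry label, sex chromosomes (all samples are treated as diploid
everywhere, including X-linked genes), sequencing error, and genotype
missingness (the reader handles missingness; the generator does not produce
it).  Passing recovery tests therefore show the pipeline's statistical
machinery is correct under its own assumptions, not that those assumptions
hold in real exome data.

## Built-in experiments

`fasdvar.experiments` packages three seed-driven validation experiments used
by the test suite and `scripts/acceptance.py`:

* **Null calibration** — one 2000-variant all-null cohort for the rejection
  rate at α, plus 60 replicate 2000-variant null cohorts for the empirical
  FDR (every BH rejection under the null is false, so per-replicate FDR is
  V/max(R, 1)).
* **Recovery** — 500 replicate cohorts, each with one variant planted at
  OR 5 over reference frequency 0.25 among 29 null variants; recovery means
  BH-significant *and* classified risk.  A committed power table
  (`tests/data/power_reference.tsv`, `power_experiment` at seed 97, 500
  replicates per cell) freezes the package's own power figures across an
  OR × frequency grid.
* **Burden separation** — 64 variants in 32 genes; RA and WNT variants are
  rare in the reference (2.5%), and the planted arm gives FAS members ≈ 6
  extra risk alleles in RA (1 in WNT) and pFAS members the mirror image, so
  both groups carry the variants (keeping them FAS∕pFAS-common through the
  inclusion rules) while their pathway profiles differ.  The planted arm
  runs the complete pipeline; the matched null arm scores the same
  candidate pathway variants on an unplanted cohort (bypassing the
  significance gate a null cohort cannot pass) to calibrate the silhouette
  near zero.

## Numerical choices

* Reference counts: round half away from zero, clamped to [0, AN].
* p-values are floored at the smallest positive double so they stay in
  (0, 1].
* BH uses a stable sort; the threshold is exactly k·α/n.
* PCA keeps all min(n, p) components, so reconstruction
  (scores · loadingsᵀ · scale + mean) is exact on full-rank input.
* Degenerate inputs are explicit: all-missing variants error in
  single-variant calls and are dropped with a warning in table scans;
  all-identical burden rows yield a degenerate PCA result rather than NaNs.

## Known limitations

* **FDR control is approximate at 46 chromosomes.**  Pearson chi-squared
  p-values are well calibrated at α = 0.05 for this design (measured null
  rejection rate ≈ 0.05), but in the far tail — exactly where BH's step-up
  criteria k·α/m live — the chi-squared approximation to the discrete
  Binomial(46, f) cohort count is anti-conservative, increasingly so for
  reference frequencies near the 0.05/0.95 bounds.  Exact enumeration shows
  P(p ≤ t) reaching ~1.7–2.6 × t at t = 10⁻⁴–10⁻⁵.  BH assumes
  super-uniform p-values, so its nominal FDR guarantee does not strictly
  hold here: the built-in null-calibration experiment measures an empirical
  FDR above α (and the corresponding assertion in the test suite documents
  this as an expected failure).  Yates correction reduces but does not
  remove the effect, at the cost of a conservative raw rejection rate.
  Strict control would require an exact test, which the emulated
  chi-squared methodology does not use; practitioners should treat
  borderline BH-significant calls at this cohort size with caution.
* Relatedness (sibling pairs) and ancestry stratification are not adjusted
  for; ancestry labels are surfaced so the contrast can be inspected, not
  corrected.
* All samples are treated as diploid; hemizygous males at X-linked genes
  are counted as two alleles.
* Whether per-person burden should be dosage or carrier status is a design
  choice (dosage here); the alternative is a one-line change at the scoring
  call.
* The fixed-total-test-count BH convention mixes tested and whitelisted
  variants; the package takes it as an explicit override rather than trying
  to reconstruct any particular historical count.
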