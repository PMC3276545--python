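# Methods

This note documents the models implemented in `reporterscreen`, the choices
made where the procedure admitted more than one reading, and what the
synthetic-data generator does and does not emulate.

## Phenotype and Z-score

Flow-cytometry events carry log10-transformed forward scatter (`fsc`, a
proxy for cell size) and fluorescence channels (`yfp`, `cfp`), all in
arbitrary units. Events are gated to a closed FSC window (default
[5.30, 5.55] log10 units; a percentile-based gate at the 20th/80th FSC
percentiles is available for instruments with different ranges — which gate
applies to which dataset is a configuration choice).

A culture's phenotype is the **median over gated events of the per-event
ratio log10(fluorescence)/log10(FSC)**. "Median ratio after log
transformation" admits a second reading — the median of
log10(fluorescence) − log10(FSC), i.e. the log of the linear-scale ratio —
which is available via `mode="log-of-ratio"`; the default follows the
literal ratio-of-logs reading. Within the narrow FSC gate the two are
monotonically related and lead to the same mutant calls.

The Z-score of a culture is (value − mean of replicate controls) / sample
standard deviation (n−1 denominator) of the controls. Control replicate
counts in this design are small-to-moderate (10–143), which is why the
sample sd is used. A culture is a **mutant** when |Z| strictly exceeds the
two-sided normal critical value (2.58 at p < 0.01); a diploid heterozygote
is **recessive** when |Z| is strictly below the same threshold. Using
strict inequalities on both sides keeps the two calls complementary at the
boundary. The same standardization applied to the per-culture variance of
the event-level ratio yields a variance Z-score for detecting
noise-increasing mutants.

## Mutant frequency and Poisson load

`tail_excess_frequency` compares the per-cell phenotype distributions of a
mutagenized and a control population:

1. Both samples are binned on a shared equal-width grid (default 256 bins).
   The grid spans the pooled sample clipped to its [0.1, 99.9] percentile
   span — the analogue of a cytometer's plotted range, which excludes a
   small fraction of extreme events. Without clipping, a handful of
   extreme-phenotype cells (e.g. fluorophore-destroying coding mutants)
   stretch the range so far that the central mass collapses into a few
   bins and the difference curve loses all structure. Cells beyond the
   clipped range are unambiguous tail excess and are counted directly
   (minus any scaled control overflow).
2. Control counts are scaled to the treated total and subtracted per bin.
3. A cubic smoothing spline is fitted to the per-bin difference, with the
   smoothing parameter chosen by generalized cross-validation
   (`scipy.interpolate.make_smoothing_spline`); a fixed smoothing value can
   be supplied instead.
4. Zero crossings are located as sign changes of the spline on a 1,000-point
   grid, refined by bisection; the innermost crossing pair bracketing the
   control median delimits the unchanged central mass. Fewer than two
   interior crossings raises a degenerate-screen error (identical inputs
   return f = 0 with a degenerate flag; the pipeline treats a crossing-less
   screen as f = 0 rather than aborting).
5. **f** is the sum of positive raw-bin differences outside the crossings
   (plus overflow excess), divided by the treated total. The spline is used
   only to locate the crossings, not to measure the excess, mirroring an
   analysis in which raw count differences and their spline fit are
   separate curves. A `use_spline_excess` switch integrates the positive
   spline instead, since which variant was used in practice is not
   documented.

Under a Poisson model of per-genome mutation counts, the fraction of
genomes with no activity-affecting mutation is p₀ = 1 − f, so the mean load
is λ = −ln(p₀), with p₁ = λe^(−λ) and p₍>1₎ = 1 − p₀ − p₁. Dividing λ by
the mutagen's fold-elevation of a calibrated marker rate (observed marker
frequency / reported spontaneous marker rate) gives a spontaneous rate per
haploid genome per generation. This assumes the mutagen targets sites
affecting the marker and the reporter in similar proportion.

f is a *detectable-mutant* frequency: mutations whose effects lie inside
the crossing interval are invisible to any tail-based estimator, so λ̂ is
biased downward when small effects are common. Parameter-recovery tests
therefore plant large effects when validating the estimator's calibration,
and the recovery bound (<10% relative bias at λ ∈ {0.01, 0.03, 0.1},
n = 10⁶ cells) applies to that regime.

Sorting-purity arithmetic: if a sorting threshold captures s_c % of the
control population and s_t % of the treated population, the expected mutant
fraction among sorted treated cells is (s_t − s_c)/s_t (clipped at zero
with a warning if the control tail is wider). Expected mutant yields per
tail are n_sorted × colony-formation rate × purity;
`expected_direction_fraction` reports both tails' shares of the total.
Published accounts of this design pair the two purity values with the two
tails inconsistently between passages, so the operation reports both shares
and privileges neither.

## Classification

Evidence per mutant: at most one reporter-transgene substitution (position
in TSS-relative coordinates, no position 0) and a pyrosequencing
copy-number assay. Coordinates are mapped to promoter/CDS/terminator spans
by inclusive-interval membership; the TSS→ATG offset is a required
annotation field, not a constant, because it is construct-specific. CDS
substitutions are translated codon-wise with the standard nuclear code
(reference-base mismatches are data-integrity errors); a stop gain is
"nonsense".

The pyrosequencing YFP allele fraction has expectation n/(n+1) for n focal
copies against one reference copy. The caller uses the midpoint 7/12
between the one-copy (1/2) and two-copy (2/3) expectations, with an
indeterminate buffer of ±2 binomial standard errors at the observed read
depth (observed clusters, not thresholds, are what such assays report, so
the decision rule is this package's own). Assays under 100 total reads are
flagged and left indeterminate. At 1,000 reads the misclassification
probability is below 0.1% (binomial tail).

Class assignment precedence: **coding > cis > cnv > trans**. A synonymous
CDS change is not coding evidence and falls through to the copy-number
branch (consistent with class-count arithmetic in which the one silent
mutant lands in the trans class; `strict_silent` flags it in the evidence
instead). A genotype with neither a transgene mutation nor a usable
copy-number assay is "ambiguous" — it could be a CNV or a trans mutant —
and is excluded from class comparisons. Class-frequency denominators follow
the evidence requirements: coding and cis fractions are over all assigned
genotypes, cnv and trans fractions over the copy-number-assayed subset.
Precedence is rarely exercised (no real genotype carried two transgene
mutations) but makes the assignment a total function.

## Dominance and class comparisons

Diploid measurements come from heterozygous crosses against a CFP-marked
reference; YFP reports the mutant-derived allele, CFP the reference allele.
Z-scores are computed against diploid control crosses — haploid and diploid
Z-scores are standardized against different control sets and are not
directly comparable.

The haploid→diploid slope per class uses **model II regression**, because
both axes are noisy measurements. The default is the major axis (MA): the
slope of the leading eigenvector of the 2×2 covariance matrix, appropriate
when both variables are on a common scale (Z-scores). MA is equivariant
under scaling both axes together but not under rescaling one axis alone;
the standardized major axis (sign(cov)·sd(y)/sd(x)) is available where
differential rescaling matters. Which model II variant produced previously
published slopes is not documented; only slope orderings are asserted here.

Effect-magnitude comparisons between classes use the Mann-Whitney-Wilcoxon
rank-sum test on |Z| — exact by complete enumeration of group assignments
when the pooled sample is ≤ 12 (the U distribution under permutation is
symmetric about n₁n₂/2 even with ties), and a tie-corrected normal
approximation with continuity correction otherwise. Sidedness is a
parameter (some published comparisons are one-sided). Colony-formation
comparisons use Fisher's exact test with the point-probability rule
(summing hypergeometric probabilities no larger than the observed table's).
No multiple-testing correction is applied anywhere, deliberately: the
analysis reports a small number of pre-specified comparisons.

CFP cross-effects are categorized per mutant as no effect
(|Z_CFP| ≤ threshold), same-direction, or opposite-direction relative to
the diploid YFP effect. Trans-acting mutants are expected in
same-direction, CNVs (which can silence the reference allele) in
opposite-direction.

## The synthetic-data generator

Event model: log10 FSC ~ Normal(5.43, 0.10); log10 YFP = −1.0 + 1.0·FSC +
Normal(0, 0.04), giving an FSC–YFP correlation of ≈ 0.93 and a per-event
phenotype (ratio) sd of ≈ 0.008. CFP uses the same slope with intercept
−1.05. Mutational effects are **multiplicative on linear-scale activity**,
i.e. additive shifts of log10 YFP, matching how log-scale fluorescence
shifts compose; a cell with several mutations multiplies their effects
(≈1% of mutants at the default load, so rarely exercised).

Treated populations draw K ~ Poisson(λ) mutations per cell (default
λ = 0.0303), each mutation a class from weights coding/cnv/cis/trans =
0.07/0.10/0.02/0.81 with a class-specific effect distribution:

| class  | log10-effect magnitude            | direction (+) | dominance d |
|--------|-----------------------------------|---------------|-------------|
| coding | Normal(1.8, 0.4), ≥ 0.4           | 0%            | 1           |
| cnv    | Normal(log10 2, 0.10), ≥ 0.12     | 100%          | 1           |
| cis    | Normal(0.30, 0.10), ≥ 0.05        | 50%           | 1           |
| trans  | Lognormal(median 0.175, σ = 0.5)  | 73%           | 0           |

Culture-level replicate noise of the median-ratio phenotype is 0.007
(haploid) and 0.0047 (diploid) — diploid phenotypes were measured in more
cells, and the ratio of the two (≈1.5) sets the expected haploid→diploid
slope for non-recessive classes. With these defaults the class-median |Z|
land near 48 (coding), 8 (cnv and cis), and 5 (trans), reproducing the
observed ordering; these are calibrated defaults, not truths, and the
distribution family of trans effects in particular is unknown — it is
exposed as configuration rather than asserted. The CNV magnitude is spread
around exactly ×2 dosage because real duplications modulate expression;
without spread, every CNV has the same effect and a within-class regression
slope is undefined. In diploid crosses, allele-specific classes (coding,
cis, cnv) shift YFP only, scaled by d; trans mutations shift both channels
by d times their effect; a CNV additionally multiplies CFP by
`cnv_cfp_effect` (default 0.8, making its reference-allele suppression
reliably significant). Pyrosequencing reads are
Binomial(1000, copies/(copies+1)).

One `SeedSequence` per dataset spawns deterministic sub-streams per stage
and per genotype, so a fixed seed is bit-reproducible and independent of
which components are consumed.

What the generator does **not** emulate: real per-cell biological
variability (its event noise is purely instrumental, so mutant and control
distributions separate more cleanly than in practice); autofluorescence,
spectral overlap, doublets, and instrument saturation; cell-cycle and
growth-rate structure (no fitness effects, no sorting-survival bias);
partially dominant trans mutations (d is a per-class scalar, so the ~12%
non-recessive trans fraction and the diploid YFP–CFP slope ≈ 1 of that
subset are not reproduced); duplications larger than one extra tandem
reporter copy; and sequence-level mutagenesis outside the reporter.
Passing tests therefore demonstrate correctness of the estimators under
the stated statistical model, not robustness to these additional features
of real data.

The bundled reporter CDS (`data/synthetic_venus_cds.fasta`) is a
**synthetic stand-in** for a Venus-type YFP coding sequence: 717 nt
(238 codons + stop), 35.56% GC, free of internal stops, with a G at TSS
position +348 whose G→A transition is synonymous. The default annotation
places the promoter at −680..−1, the ATG at +34 (a construct-specific
choice, since the true TSS→ATG offset is not documented), the CDS at
+34..+750, and the terminator at +751..+1000.

## Problem sizes and numerical choices

- Default screen: 231 mutant genotypes, ≥5,000 events per haploid culture,
  ≥9,000 per diploid culture, 20 control replicates, 50,000-cell primary
  populations. Test and validation runs scale populations and genotype
  counts to keep the suite fast while preserving the statistical structure
  (e.g. λ recovery at 10⁶ cells, false-positive calibration at 1,137
  control cultures, dominance slopes at the full 231 genotypes).
- Equality tolerances: class probabilities sum to 1 within 10⁻¹²; exact
  test p-values match enumeration within 10⁻¹²; crossings are refined by
  bisection to scipy's default tolerance.
- Degenerate inputs are first-class: empty gates raise a distinct error
  from empty inputs; zero control sd, zero reads, position 0, and
  reference-base mismatches all raise with specific messages.

## Known limitations

- The tail-excess estimator's downward bias with small effects is inherent
  to the method, not a bug; it estimates detectable-mutant frequency.
- MA regression slopes on small classes (n < ~10) are noisy; the package
  reports them but analyses should lean on orderings, as the tests do.
- The spline-crossing locator assumes a unimodal central mass; strongly
  multimodal controls would need a different delimitation rule.
- Copy-number calls distinguish one vs two copies only; higher
  amplifications would need additional expected-fraction thresholds
  (n/(n+1) generalizes, the default thresholds do not).
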