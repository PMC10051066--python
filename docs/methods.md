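# Methods

This note documents the models behind `msapop`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real MSAP data.

## Fragment scoring and the MSL/NML partition

Each locus × individual cell combines the EcoRI–HpaII and EcoRI–MspI
presence calls into one of four states: U (1/1, non-methylated),
H (1/0, hemimethylated), I (0/1, internal cytosine methylation),
F (0/0, hypermethylated or genetically absent).  Scoring is purely
cell-wise; missing calls propagate, never imputed.

A locus is **MSL** when its proportion of methylated scores (H, I, F among
non-missing cells) *strictly* exceeds the threshold (default 0.05; the
boundary case — exactly 5% — falls to NML, and both classifier branches are
exercised in the tests).  The **polymorphism** rule is applied at the state
level: at least two distinct observed states, each occurring at least
twice, which removes singleton-driven loci.  A locus is **retained** when
it is additionally informative after binary encoding — at least two cells
on each side of its 0/1 encoding.  Without that second condition a locus
such as H×10/I×10 would be state-polymorphic yet constant in the epigenetic
matrix; adding it keeps every retained column usable by distance-based
statistics.

**The 0/0 ambiguity.** A doubly absent band can mean hypermethylation or a
genetic absence.  The default counts F as methylated in both the binary
epigenetic encoding and the per-individual methylation frequency; the
`f_as_missing` toggle treats F cells as missing instead, for sensitivity
analyses.  At NML, band presence is defined as presence in at least one
digest (at a methylation-insensitive locus both digests should cut
identically, so either band evidences the allele).

A structural consequence worth knowing: at very small sample sizes the two
rules interact — a retained NML needs ≥ 2 absences, but 2 absences out of,
say, 12 individuals already exceed the 5% methylated-score threshold, so
tiny studies (such as the shipped toy fixture) legitimately have an empty
genetic marker set.  With ~200 individuals the window 2–10 absences is wide
and the partition behaves as in real surveys.

## QC filters and the error rate

Filters run in a fixed order: size window (default 50–400 bp, from
fragment metadata), rarity (presence *or* absence in exactly one
individual, evaluated in either digest), then — on the survivors — the
replicate-plate reproducibility screen: a fragment is dropped when its
within-population band frequency differs by more than 0.15 between the two
plates in *any* population, in either digest (the per-population,
any-violation reading is the conservative one).  An RFU floor belongs at
matrix construction: `presence_from_peak_table` scores peaks below the
threshold (default 100 RFU) as absent.

The between-run error rate follows the standard replicate-concordance
formula literally: discordant cells × 100 / (n_fragments × n_individuals),
computed separately per digest set on raw presence calls; cells missing in
either run count as concordant.  A state-level discordance is reported as a
diagnostic only (one flipped band can change the state, so it runs roughly
twice the per-digest rate).

## Differentiation statistics

All molecular distances are squared Euclidean on binary rows — the
standard choice for dominant markers — with pairwise rescaling by
L/L_shared when cells are missing.  AMOVA follows the classical
sums-of-squared-deviations construction: SSD_total and SSD_within come
directly from the distance matrix, variance components from the expected
mean squares with unequal sample sizes (coefficient
n′ = (N − Σn_p²/N)/(P−1)), and Φ_ST = σ²_a/(σ²_a + σ²_w).  Negative
components are truncated to zero for the reported Φ and percentages (raw
values are kept in the result object), so the identity
Φ_ST = among-% / 100 holds exactly on every report.

**Permutation tests.**  p = (b+1)/(m+1), one-sided.  The permutation
statistic is *untruncated*: because SSD_total is invariant under
relabelling, a smaller within-group SSD is exactly a larger Φ, so the
one-level test (and the individual-level test in the two-level design)
compares SSD_within directly.  Truncating the statistic would pile half the
null distribution at Φ = 0 and send every negative-component dataset to
p = 1; the SSD statistic keeps null p-values uniform (verified by KS in the
acceptance suite).  The two-level design (populations nested in groups,
used for the low/high imposex pooling) tests the among-groups level by
permuting whole populations among groups with the raw among-groups
component as the statistic.

Pairwise Φ_ST runs a two-population AMOVA per pair (default 100
permutations, α = 0.05); negative estimates are reported as zero.  A 3+3
fixed difference can never be significant at α = 0.05 — the exact
permutation p is ≈ 0.107 because the complementary relabelling also attains
Φ = 1 — which the tests assert explicitly.

**Diversity.**  Per locus and population the null-phenotype frequency x
gives q̂ = √x, clipped to [1/(2n), 1 − 1/(2n)] for polymorphic loci;
monomorphic loci return the exact closed forms (Ne = 1, h = 0, I = 0) —
clipping them too would contradict the closed-form limits.  Ne, Nei's h and
Shannon's I are averaged over loci.  The Lynch–Milligan small-sample
correction is deliberately not applied; the estimator is an explicit
extension point.  MSL and NML receive the same estimator so the epigenetic
and genetic indices are comparable side by side.

**PCoA** treats its input as *squared* dissimilarities (matching the
package's distance), so Gower centring is B = −½ J D J and coordinates
from known points are recovered exactly (Procrustes-checked).  Percent
variance uses positive eigenvalues only; negative eigenvalues are counted
and reported, never silently dropped.  **Mantel** correlates lower
triangles with joint row/column permutations, one-sided greater (isolation
by distance is directional), seeded.

## The outlier scan

The scan is an Fdist/Dfdist-style genome scan adapted to dominant data:

1. **Zhivotovsky estimation.**  Per population, a Beta(a,b) prior on the
   null-phenotype frequency x is fitted by moments across loci, with the
   across-locus variance corrected for binomial sampling
   (Var(x̂) ≈ σ²(1−1/n̄) + x̄(1−x̄)/n̄; a non-positive corrected variance is
   floored at 10⁻⁴·x̄(1−x̄) with a warning).  The per-locus estimate is the
   posterior mean of q = √x, E[√x | m of n] in closed Beta-function form
   (quadrature-verified to 10⁻⁶).  Estimates are strictly interior to
   (0,1).  The prior is fitted per population by default; a pooled-prior
   option exists (the original description leaves the pooling unstated).
2. **Locus statistics.**  H_S is the unweighted mean within-population
   2q(1−q); H_T uses the sample-size-weighted pooled frequency;
   FST = (H_T − H_S)/H_T.  Loci with H_T = 0 are skipped with a note.
3. **Neutral envelope.**  Simulated loci draw an ancestral null frequency
   uniform on (0.01, 0.99) and population frequencies from the
   Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F); null phenotypes are
   binomial with probability q².  Simulated counts pass through *the same*
   fitted priors as the observed data, so observed and simulated loci share
   one estimator.  Short trial batches adjust the input F until the
   realized mean simulated FST matches the target ("force mean FST"
   behaviour), making the mean-calibration property hold by construction.
4. **Flagging.**  Equal-count He bins (default 25, merged with a warning
   when simulations are scarce) carry the lower, median and upper
   (one-sided, default 0.99) FST quantiles.  Lookup is **by bin
   membership, not interpolation**: the Bayesian estimator concentrates
   near-monomorphic loci at a few He atoms where the conditional FST
   distribution is discontinuous, and interpolation across those atoms
   demonstrably inflates the false-positive rate severalfold; within a
   bin, observed and simulated loci are exchangeable, so the nominal tail
   rate is recovered (acceptance-tested at 10,000 simulations).  The
   default performs one trim-and-recalibrate pass: flagged loci are
   removed, the remainder's mean FST becomes the new target, the envelope
   is re-simulated once and all loci re-flagged ("neutral FST"); a
   user-supplied `force_mean_fst` skips recalibration.  Low-tail loci are
   reported but never flagged.

Applying a diploid-dominant scan to MSL methylation bands is a model
misfit inherited from practice (methylation states are not alleles of a
diploid locus); on generator MSL data the scan therefore flags somewhat
more than the nominal 1% even without planted effects.  The calibration
guarantees hold for data generated from the scan's own null, which is what
the acceptance suite checks; planted strong effects (frequency contrast
0.05 vs 0.95) are recovered with power > 0.8.

## Phenotype models

The proportional-odds model maximises the cumulative-logit likelihood
P(y ≤ k) = logistic(ζ_k − x'β) by Newton iterations with step-halving
(monotone in the likelihood), parameterised by (β, ζ₁, log Δζ) so the
cutpoints stay ordered.  Predictors are standardised internally and the
fit transformed back; this conditions the optimisation and makes t, p and
AIC exactly invariant to predictor rescaling.  Standard errors come from
the observed information (central-difference Hessian) in the standardised
natural parameterisation, mapped through the exact Jacobian.  Convergence
requires the standardised score's max-norm below 10⁻⁸; a standardised
coefficient beyond ±15 raises a separation error naming the predictor.
Declared response levels with zero counts are collapsed into the adjacent
category with a warning (their cutpoints are unidentifiable).  Wald
summaries use the normal reference (t = β̂/SE, OR = e^β̂,
CI = e^{β̂±1.96·SE}); a printed CI that is not Wald-reproducible from its
printed estimate and SE is a known discrepancy of such tables and is not
asserted anywhere.  AIC = −2ℓ + 2(len β + K − 1) holds exactly on every
fit.

OLS, one-way ANOVA and Tukey HSD delegate to statsmodels (Tukey–Kramer for
unequal n); the compact letter display assigns one letter per maximal
clique of the non-significance graph, ordered by group mean.  Mann–Whitney
uses exact enumeration for tie-free groups of ≤ 8, otherwise the normal
approximation with tie correction.  Trait PCA offers allometric
normalisation (log trait − log reference length, the length column
excluded) or z-scoring; constant columns are dropped with a warning.

## The synthetic-data generator

The generator emulates the survey structure end to end: 7 populations × 30
individuals; population mean TBT burdens (1.8, 2.6, 10.7, 21.4, 27.5,
34.9, 43.1 ng Sn g⁻¹ — two low, one intermediate, four high sites, the
high values evenly spanning the reported 21.4–43.1 range); 355 MSL and 43
NML input loci; individual TBT lognormal around the population mean
(σ = 0.5, a typical tissue-burden CV); TBT chemistry "measured" on 9
females per population (as in field practice, the rest missing).

**FST calibration.**  The configured `fst_epi` (0.026) and `fst_gen`
(0.010) are *band-level* AMOVA targets, because the emulated Φ_ST values
are themselves band-level statistics.  For MSL, the TBT-driven spread of
population methylation means (logit shift `methylation_slope`, default
−0.008 per ng Sn g⁻¹, a population-level effect) is charged against the
among-population variance budget fst_epi·μ̄(1−μ̄) at the P/(P−1)
fixed-effect rate; residual island Beta noise supplies the remainder, and
a configuration whose gradient alone exceeds the budget at more than 10%
of loci is rejected before sampling.  For NML the island variance on the
null-allele frequency is delta-method-inflated by (2q)⁻² to the band
scale; ancestral null frequencies are kept low (0.12–0.20) so double
absences stay below the 5% MSL threshold.  Realized multi-locus Φ_ST is
0.0264 ± 0.0012 (epigenetic) and 0.0096 ± 0.0039 (genetic) across seeds —
the acceptance suite asserts 3-Monte-Carlo-SD agreement.

**Phenotypes.**  Methylated mass splits H:I:F at 40:40:20 (the source
gives no state composition).  Imposex is drawn from a proportional-odds
model on (TBT, methylation) with β = (0.03, −47.17) — the two univariate
coefficients of the emulated survey used jointly — and default cutpoints
chosen on the latent scale so low-TBT populations are mostly levels 1–4
and high-TBT populations mostly 5–8, the survey's qualitative pattern.
Because the generating model is joint while the fitted models are
univariate, the pipeline's univariate TBT slope (~0.06) exceeds the
configured 0.03 by omitted-variable amplification; parameter-recovery
tests therefore generate directly from the ordinal sampler with fixed
design.  An individual-level methylation "leak" slope (default 0) lets the
individual-level TBT→methylation regression be null while the
population-level one is strong, as observed.  Mass is linear in TBT,
methylation and imposex with Gaussian noise.  Coordinates are drawn
uncorrelated with differentiation (no isolation by distance).

**Plate noise.**  Replicate plates rescore 24 individuals with independent
per-cell flips at `plate_error_rate` (default 0.021, giving a between-run
discordance 2e(1−e) ≈ 4.1% on retained fragments, the post-filter error
level of the emulated survey).  A single flat flip rate cannot also
reproduce an 11% pre-filter rate; that contrast is instead carried by the
junk fragments — one third out-of-size, one third singletons, one third
with gross directional plate-B shifts (rate 0.45) that the 0.15
reproducibility rule catches.

**What passing tests show.**  The generator shares the analysis's
distributional assumptions (Balding–Nichols frequencies, multinomial
states, proportional odds), so recovery tests validate the *estimators and
their calibration*, not the robustness of the method to real MSAP
artefacts: size homoplasy, co-migrating fragments, peak-calling bias near
the RFU floor, linked loci, or methylation states that violate the
diploid-dominant reading of band patterns.  Conclusions about real data
rest on the QC filters and on the scan's documented model misfit above.

## Numerical conventions

- Permutation p-values are (b+1)/(m+1); ties count as exceedances
  (conservative).
- All randomness flows from explicit integer seeds; the pipeline derives
  one child seed per stochastic stage from its config seed, so reports are
  byte-identical across reruns.
- Distances: pairs sharing zero scored loci are an error, not NaN.
- Default problem sizes (7×30 individuals, 10,000 scan simulations, 1000
  AMOVA / 100 pairwise permutations) match the emulated survey; the test
  suite uses the same sizes for calibration-sensitive checks and smaller
  instances where only exact identities are at stake.
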