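# Methods

This note documents the models, numerical choices and limitations behind
`bcprs`.  Everything quantitative stated here is computed by the test suite
or the acceptance script; nothing is asserted from memory.

## Disease model and synthetic cohorts

Individuals carry effect-allele dosages x_k drawn per SNP from
Hardy–Weinberg proportions ((1−p)², 2p(1−p), p²) with independent loci (no
linkage disequilibrium; the panel's `region_id` groups exist to exercise the
linked-SNP pruning path, not to induce correlation).  Disease risk is
multiplicative in the score s = Σβ_k x_k plus a residual polygenic liability
u: risk ∝ exp(s + u).

**Retrospective sampling by exponential tilting.**  For relative risk
e^{βx}, the genotype distribution among cases is the population distribution
reweighted by e^{βx} per SNP.  Case genotypes are therefore drawn directly
from the tilted per-SNP multinomials — exact under the multiplicative model
with independent loci, with no rejection sampling from a population pool
(which also means an "unreachable case count" failure mode does not exist;
only configuration validation can fail).  For a Normal(μ, σ²) score this
tilting shifts the case distribution to Normal(μ + σ², σ²); the test suite
verifies the generated case scores are within Kolmogorov distance 0.01 of
that normal at n = 10⁵.

**Panel construction.**  Effect-allele frequencies are uniform on
`eaf_range` (default 0.05–0.95).  Per-allele log ORs for the three endpoints
(overall, ER-positive, ER-negative) are drawn jointly normal with pairwise
correlation `endpoint_corr` (default 0.7 — most susceptibility loci are
shared across subtypes, a minority is subtype-specific), oriented so the
effect allele is the risk allele for overall disease, then rescaled by one
constant per endpoint so that sqrt(Σ 2p(1−p)β²) equals the target SD
*exactly* (defaults 0.45 / 0.50 / 0.38).  Because a single multiplicative
constant is used, magnitudes vary across SNPs (realistic); with all
frequencies equal the root-mean-square |β| equals target/sqrt(K·2p(1−p)).

**Age interaction.**  The fitted model for effect modification by age is
logit P(case) ~ z + (age−50)/10 + z·(age−50)/10 + covariates, with z the
standardised score; "OR per 10 years" is exp of the product-term
coefficient.  The generator therefore makes the per-SD log OR at age a equal
σ + ln(or10)·(a−50)/10 (additive in the coefficient, the parameterisation
the fitted model estimates), implemented by scaling each case's tilting
strength.  Default or10 = 0.98.  The age main effect is included in the
fitted design whenever the product term is: the generator induces a mild age
gradient in case probability (the tilt normaliser e^{c(a)²σ²/2} varies with
age), and omitting the main effect would let that gradient contaminate the
interaction estimate.  Case and control ages are drawn from the same
distribution (Normal(56, 8) clipped to [25, 79]), so there is no
case-control age confounding by construction.

**ER subtype.**  Each case's subtype is drawn with probability proportional
to π·exp(c·z⁺ − c²σ⁺²/2) versus (1−π)·exp(c·z⁻ − c²σ⁻²/2), where z± are the
centred subtype-specific scores and π = `er_pos_case_fraction` (default
0.78).  This keeps the marginal ER-positive fraction near π while letting
the subtype scores govern which subtype arises.  The overall-endpoint tilt
uses the overall weights, so per-SD recovery for the overall score is exact;
subtype-endpoint fits are approximate by design.

**Family history.**  The total polygenic liability is G = (s − E[s]) + u
with Var(G) = σ_T² = 2·ln(fh_frr), so the implied first-degree FRR
exp(σ_T²/2) equals `fh_frr` (default 2).  Each individual gets one simulated
first-degree relative with liability correlation ½; the relative's lifetime
affection probability is K·exp(G_r − σ_T²/2) with K =
`relative_lifetime_risk` (default 0.10), capped at 1.  Two consequences
worth knowing:

* The *odds ratio* of family history for case status exceeds the FRR —
  analytically FRR·(1−K)/(1−K·FRR) ≈ 2.25 at FRR 2 and K 0.1, reduced
  slightly by the probability cap and the age-decay of the tilt; the
  simulated value at n = 50 000 lands near 2.0–2.2.
* When fh_frr < exp(σ_PRS²/2) the requested total liability variance is
  smaller than the PRS component alone — physically impossible — so the
  liability is shrunk onto the PRS with a warning; fh_frr = 1 then yields
  exact independence.

The PRS fraction of the liability variance, σ²/σ_T² ≈ 0.146 at σ = 0.45 and
FRR 2, is the expected log-scale attenuation of the FH odds ratio after PRS
adjustment; simulated cohorts reproduce ≈ 14%.  The model uses one binary
relative; number and ages of relatives are not modelled.

**Nuisance covariates.**  Study labels (4 studies) and 7 principal
components are inert (confounding 0): they exercise the adjustment code
paths without biasing estimates.

**What the generator does not emulate:** linkage disequilibrium, genotyping
error and missingness patterns, imputation uncertainty, population
stratification that correlates with the phenotype, study heterogeneity in
effect sizes, and oversampling by family history.  Passing tests show the
estimators are correct under the generating model, not that real-data
artefacts are handled.

## Scores, bins and fits

Raw scores are Σβx with missing dosages imputed at 2·eaf (`mean_dose`,
default; the alternative `drop_individual` flags the score as absent rather
than silently zeroing).  Residual scores are standardized Pearson residuals
from OLS of the score on indicator-coded study + PCs: (score − fit)/SD,
mean 0 and SD 1 by construction; collinear design columns are dropped with a
warning.

Percentile cutpoints are empirical quantiles (type-7 linear interpolation)
of the **control** score distribution — controls approximate the population
in a case-control design — at boundaries 1/5/10/20/40/60/80/90/95/99%, with
intervals lower-open/upper-closed and the 40–60% bin as reference.  Bins are
cut on raw scores by default (a flag selects residual scores); covariate
adjustment happens inside the regression instead.  Binning is invariant to
strictly increasing transforms of all scores.

Association fits are logistic regressions with Wald tests and CIs
throughout (profile likelihood is out of scope).  ER-subtype endpoints fit
subtype cases against the full control series with the subtype-specific
score.  The C-statistic is the Mann–Whitney AUC with midrank ties and a
DeLong asymptotic CI, kept separate from the binormal closed form
Φ(β_SD/√2) so the two routes cross-check each other.  Percent attenuation of
the family-history OR is 100·(ln ORu − ln ORa)/ln ORu, undefined when
ORu ≤ 1 (flagged, not fabricated).  Strata too sparse to fit are flagged
with NaN rather than aborting the analysis.

## Interaction scan

Case-control mode: status ~ covariates + het/hom indicators for each SNP +
the continuous dose product, 1-df Wald on the product coefficient, doses on
the risk-allele orientation.  Wald was chosen over a likelihood-ratio test
for speed at scan scale; the per-pair type-I error at α = .01 is verified to
sit inside the binomial 99% band under the null.  Case-only mode: linear
regression of dose on dose within cases — the standard case-only
approximation, valid when the loci are independent among controls — with the
same regression within controls as the screen (pairs with control-only
P ≤ α are excluded from case-only counts).  Linked SNPs share a `region_id`;
the unlinked scan keeps the SNP with the smallest main-effect P per region
and never tests within-region pairs.  Non-converged fits are dropped from
both numerator and denominator, with the count logged.

The summary compares the observed number of significant pairs with
expectation n·α: ratio obs/(n·α) (displayed to 2 dp), a two-sided Poisson
P = min(1, 2·min(P(X ≤ obs), P(X ≥ obs))), and a two-sided binomial test of
the synergistic fraction against ½.  Direction is the sign of the product
coefficient under risk coding, undefined when it or a main effect is exactly
zero.

## Absolute risk

Annual discrete hazards with exponential within-year survival, risks
accruing from age 20 (incidence below 20 treated as zero):

    S(t+1) = S(t)·e^{−h−μ},   A(t+1) = A(t) + S(t)·(h/(h+μ))·(1 − e^{−h−μ})

with h = λ0(t)·rr_k.  The baseline λ0 = λ/Σp·rr makes the category-average
hazard reproduce population incidence exactly (tested to 1e−12); for
constant hazards the recursion telescopes to h/(h+μ)·(1 − e^{−(h+μ)T})
(tested to 1e−10).  ORs stand in for relative risks under the rare-disease
assumption.  Ten-year risks restart the recursion at the conditioning age;
the screening threshold is the population-average 10-year risk at 47
computed from the supplied rate table, never a hard-coded 2.4%.

ER subtypes split incidence by the registry ER-positive proportion,
constrain each subtype baseline with its own relative risks, and accumulate
each subtype's risk against the joint survival; with unit relative risks the
subtype risks sum exactly to the all-cause computation.  Family-history
strata form joint categories bins × {FH, no FH} with multiplicative relative
risks and a baseline re-constrained over the joint set (the empirically
supported multiplicative joint model); the PRS-adjusted FH odds ratio is the
recommended input to avoid double counting the PRS.  Because cumulative risk
is a concave functional of the hazard, a prevalence-weighted mixture of
stratum *curves* equals the curve of the average *hazard* only in degenerate
cases (fh_or = 1); the exact identities tested are hazard conservation, the
degenerate equality, and the internal consistency of the joint-set mixture.

Confidence bands propagate the sampling distribution of the log relative
risks by parametric simulation from MVN(log rr, Σ) — re-constraining the
baseline per draw, reporting pointwise 2.5/97.5 percentiles — which handles
the nonlinear risk functional without linearisation; the delta method is
retained only as a test oracle (agreement within 5% for a single perturbed
category at 10⁴ draws).

## Synthetic rate table

Incidence follows a logistic ramp in age (midpoint 52, width 8), zero before
20, with the plateau calibrated by root finding so the cumulative risk from
20 to 80 with competing mortality equals 10% (a realistic Western lifetime
breast-cancer risk); other-cause mortality is Gompertz 2·10⁻⁵·e^{0.098·t}
(≈10⁻³ at 40, ≈0.05 at 80, typical of female all-cause-minus-breast
mortality); the ER-positive proportion is 0.70 + 0.0016·t (≈0.78 midlife).
These are synthetic stand-ins for national incidence/mortality tables and
registry ER proportions, which are not redistributed; absolute-risk figures
produced with them are structurally, not numerically, comparable to
published national estimates.

## Determinism and problem sizes

All randomness flows from integer seeds through numpy `default_rng`; the
pipeline derives per-stage substreams by hashing the stage name, so stages
are reproducible in isolation and a seed reproduces byte-identical outputs.
Test problem sizes were chosen so each statistical check has the power it
needs at desk scale: 10⁵–10⁶ draws for distributional and AUC checks, 20
replicate cohorts at 20 000 cases + 20 000 controls for parameter-recovery
coverage, and 40 null scans of 66 pairs (2 640 tests) for scan calibration.

## Known limitations

* VCF allele matching is literal; ambiguous A/T and C/G variants are matched
  by allele identity only (no frequency-based strand inference) — the panel
  file is the source of truth.
* Multi-allelic or haplotype-defined loci are treated as independent
  biallelic SNPs.
* No PLINK bed/bim/fam support, imputation-quality filtering or liftover.
* The split-sample validation design is supported only as a generic
  train/evaluate split on synthetic data; no study-heterogeneity
  meta-analysis; no higher-order (3-way+) interaction tests; no
  full-pedigree risk integration.
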