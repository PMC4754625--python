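# bcprs

Polygenic risk score (PRS) stratification for breast cancer: a tested,
reusable implementation of the full analysis pipeline — synthetic
case-control cohorts, a 77-SNP PRS, an all-pairs SNP×SNP interaction scan,
closed-form predictions under the multiplicative polygenic model, empirical
association fits, and absolute risk curves that account for competing
mortality.

## The problem

Dozens of common variants are individually weak breast-cancer risk factors,
but their combined effect stratifies women into clinically meaningful risk
groups.  The standard instrument is the polygenic risk score

    PRS_i = Σ_k β_k · x_ik

where x_ik ∈ {0, 1, 2} counts the effect alleles carried by woman *i* at SNP
*k* and β_k is the per-allele log odds ratio.  Under the multiplicative
(log-additive) model — which an all-pairs interaction scan can check — the
score is Normal with SD

    σ = sqrt( Σ_k 2·p_k·(1−p_k)·β_k² )

under Hardy–Weinberg equilibrium (p_k = effect-allele frequency), and the
theory yields closed forms for the quantities clinicians care about:

* **OR by percentile bin.**  With relative risk ∝ e^z and z ~ N(0, σ²) among
  controls, the mean relative risk of the percentile slice (a, b] is
  R(a,b) = [Φ(Φ⁻¹(b) − σ) − Φ(Φ⁻¹(a) − σ)] / (b − a); the predicted OR for a
  bin versus the middle quintile is R(bin)/R(40–60%).
* **Discrimination.**  AUC = Φ(β_SD/√2) for a per-SD log OR β_SD
  (equal-variance binormal model).
* **Familial relative risk.**  A score of SD σ implies a first-degree FRR of
  exp(σ²/2), hence the expected attenuation of the family-history OR after
  PRS adjustment.
* **Absolute risk.**  Per-category hazards λ0(t)·rr_k, with the baseline
  constrained so Σ_k p_k·λ0(t)·rr_k reproduces population incidence λ(t),
  accumulated with competing other-cause mortality μ(t).

The package is aimed at statistical geneticists and epidemiologists who want
to prototype or teach this analysis end to end.  No individual-level study
data are redistributed: a first-class synthetic-data module generates
panels, genotypes, phenotypes, family history and rate tables with the
statistical structure the analysis assumes.

## Worked example

```python
import numpy as np
from bcprs import (SimulationConfig, make_panel, make_rate_table,
                   simulate_cohort, simulate_family_history, compute_prs,
                   assign_percentiles, theoretical_sd, implied_auc,
                   predicted_or, absolute_risk)
from bcprs.association import fit_per_sd, fit_bin_ors, c_statistic
from bcprs.data_model_io import PercentileScheme

cfg = SimulationConfig(n_cases=20_000, n_controls=20_000, seed=1)
panel = make_panel(cfg)                       # 77 SNPs, score SD 0.45 exactly
genotypes, cohort = simulate_cohort(panel, cfg)
cohort = simulate_family_history(cohort, cfg)

sigma = theoretical_sd(panel)                 # 0.4500
predicted_or((0.99, 1), (0.4, 0.6), sigma)    # 3.35
implied_auc(sigma)                            # 0.625

raw = compute_prs(genotypes, panel)
labels, _ = assign_percentiles(raw, cohort.status == 0)
fit = fit_per_sd(cohort, raw, age_interaction=True)
```

Running the snippet (and the absolute-risk block that follows it in
`docs/methods.md`) prints:

```
panel SD (overall):        0.4500
predicted top-1% OR:       3.35
fitted per-SD log OR:      0.441 (95% CI 0.416 to 0.467)
age interaction OR/10y:    0.977
empirical top-1% OR:       3.11 (95% CI 2.63 to 3.68)
C-statistic:               0.619
FH OR unadj/adj:           2.18 / 1.97 (12.8% attenuation)
lifetime risk <1 bin:      2.9%
lifetime risk >99 bin:     27.1%
screening threshold:       2.09% (10-year risk at 47)
top bin crosses at age:    34
```

Reading the output: the generator hits the target score SD exactly, the
logistic fit recovers the generating per-SD log OR (0.441 vs 0.45 at age 50
after the age-interaction decay) and the interaction OR per decade (0.977 vs
the configured 0.98); the empirical top-1%-vs-middle-quintile OR (3.11, CI
2.63–3.68) is consistent with the closed-form prediction 3.35; and the
absolute-risk engine turns the predicted bin ORs plus the synthetic rate
table (calibrated to a 10% lifetime risk) into a nearly ten-fold lifetime
risk spread between the lowest and highest percentile bins, with the top bin
reaching the screening-age risk threshold 13 years before the average woman.

## Command line

The same pipeline runs from a shell, driven by a YAML config with a
mandatory global seed:

```bash
bcprs run --config config.yaml --out results/
# or stage by stage: bcprs simulate|score|scan|theory|associate|risk
```

Each stage writes TSV/CSV/JSON artifacts into the output directory and
`summary.json` aggregates the headline quantities; the same seed always
reproduces byte-identical outputs.

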