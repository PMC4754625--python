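"""Closed-form predictions under the multiplicative polygenic model.

With a polygenic score z that is Normal(0, σ²) in the population and relative
risk proportional to exp(z), the model yields closed forms for

* the score SD implied by a weight panel under Hardy–Weinberg equilibrium,
* the mean relative risk of any percentile slice of the score distribution
  (truncated-normal expectation), hence predicted ORs between bins,
* the implied C-statistic (equal-variance binormal AUC), and
* the implied first-degree familial relative risk and the fraction of an
  observed familial relative risk explained by the score.

All percentile arguments refer to the control (≈ population) distribution,
matching how the empirical bins are cut.  The global exp(σ²/2) normalising
factor cancels in every OR ratio and is never computed explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .data_model_io import SNPPanel


def theoretical_sd(panel: SNPPanel, endpoint: str = "overall") -> float:
    """Score SD implied by the panel: sqrt(Σ_k 2·p_k·(1−p_k)·β_k²).

    Assumes Hardy–Weinberg genotype frequencies and independent loci, so the
    per-SNP dosage variance is 2·p·(1−p).
    """
    p = panel.eaf
    beta = panel.betas(endpoint)
    return float(np.sqrt(np.sum(2.0 * p * (1.0 - p) * beta ** 2)))


def mean_relative_risk(a: float, b: float, sigma: float) -> float:
    """Mean of exp(z) over the (a, b] percentile slice of z ~ N(0, σ²),
    relative to the population mean exp(σ²/2).

    E[e^z | a < Φ(z/σ) ≤ b] / E[e^z] = [Φ(Φ⁻¹(b) − σ) − Φ(Φ⁻¹(a) − σ)] / (b − a),
    the standard exponential-tilting identity for a truncated normal.
    """
    if not (0.0 <= a < b <= 1.0):
        raise ValueError(f"empty or invalid percentile interval ({a}, {b}]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    hi = norm.cdf(norm.ppf(b) - sigma) if b < 1.0 else 1.0
    lo = norm.cdf(norm.ppf(a) - sigma) if a > 0.0 else 0.0
    return float((hi - lo) / (b - a))


def predicted_or(bin: tuple[float, float], ref: tuple[float, float],
                 sigma: float) -> float:
    """Predicted OR for a percentile bin versus a reference bin.

    Ratio of mean relative risks of the two truncated-normal slices; with
    σ = 0 every bin has mean risk 1 and the OR is identically 1.
    """
    return mean_relative_risk(*bin, sigma) / mean_relative_risk(*ref, sigma)


def predicted_or_table(scheme_intervals: list[tuple[float, float]],
                       ref: tuple[float, float], sigma: float) -> np.ndarray:
    """Predicted OR for each interval of a percentile scheme vs the reference."""
    return np.array([predicted_or(iv, ref, sigma) for iv in scheme_intervals])


def implied_auc(beta_per_sd: float) -> float:
    """C-statistic implied by a per-SD log OR under the binormal model.

    When case scores are shifted by ``beta_per_sd`` standard deviations with
    equal variances, AUC = Φ(β/√2).
    """
    if beta_per_sd < 0:
        raise ValueError("beta_per_sd must be non-negative")
    return float(norm.cdf(beta_per_sd / np.sqrt(2.0)))


def implied_frr(sigma: float) -> float:
    """First-degree familial relative risk implied by a polygenic score of SD
    σ: exp(σ²/2) (liability correlation ½ between first-degree relatives)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(np.exp(sigma ** 2 / 2.0))


def explained_fraction(sigma: float, observed_frr: float) -> float:
    """Fraction of an observed familial relative risk explained by the score
    on the log scale: (σ²/2) / ln(observed FRR)."""
    if observed_frr <= 1.0:
        raise ValueError("observed_frr must exceed 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float((sigma ** 2 / 2.0) / np.log(observed_frr))
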