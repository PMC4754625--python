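"""Absolute risk of disease by polygenic risk category with competing mortality.

Converts per-category relative risks (e.g. predicted or fitted percentile-bin
ORs, treated as relative risks under the rare-disease assumption) plus
population incidence λ(t) and other-cause mortality μ(t) into cumulative and
conditional 10-year absolute risks.

The baseline hazard is constrained so that the category-average incidence
reproduces the population incidence at every age:

    λ0(t) = λ(t) / Σ_k p_k·rr_k,      category hazard = λ0(t)·rr_k.

Risk accrues on a discrete annual grid with exponential within-year survival:

    S(t+1) = S(t)·exp(−h(t) − μ(t))
    A(t+1) = A(t) + S(t)·[h/(h+μ)]·(1 − exp(−h − μ)),   h(t) = λ0(t)·rr_k,

which for constant hazards reduces to the closed form
h/(h+μ)·(1 − e^{−(h+μ)T}).  Risks accrue from age 20 (incidence below 20 is
treated as 0); confidence bands propagate the sampling distribution of the
log relative risks by parametric simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model_io import RateTable

DEFAULT_AGE_START = 20
DEFAULT_AGE_END = 80


@dataclass
class RiskCurve:
    """Per-category absolute-risk trajectories on an integer age grid.

    ``cum_risk[k, j]`` is the probability of disease by ``ages[j]`` starting
    disease-free at ``ages[0]``; optional CI bands have the same shape.
    """

    categories: list[str]
    rr: np.ndarray
    p_bin: np.ndarray
    ages: np.ndarray
    cum_risk: np.ndarray
    ci_low: np.ndarray | None = field(default=None, repr=False)
    ci_high: np.ndarray | None = field(default=None, repr=False)

    def lifetime(self) -> np.ndarray:
        """Cumulative risk at the final age per category."""
        return self.cum_risk[:, -1]


def constrain_baseline(incidence: np.ndarray, rr: np.ndarray,
                       p_bin: np.ndarray) -> np.ndarray:
    """Baseline hazard λ0(t) = λ(t) / Σ_k p_k·rr_k.

    The constraint makes the population-weighted average of the category
    hazards equal the supplied population incidence at every age.
    """
    rr = np.asarray(rr, float)
    p_bin = np.asarray(p_bin, float)
    if rr.shape != p_bin.shape:
        raise ValueError("rr and p_bin must have matching shapes")
    if np.any(rr < 0):
        raise ValueError("relative risks must be non-negative")
    if not np.isclose(p_bin.sum(), 1.0, atol=1e-8):
        raise ValueError(f"bin fractions sum to {p_bin.sum()}, expected 1")
    denom = float(np.sum(p_bin * rr))
    if denom == 0:
        raise ValueError("Σ p·rr = 0: baseline hazard undefined")
    return np.asarray(incidence, float) / denom


def cumulative_risk(baseline: np.ndarray, rr_k: float, mortality: np.ndarray,
                    age_start: int = DEFAULT_AGE_START,
                    age_end: int = DEFAULT_AGE_END) -> np.ndarray:
    """Cumulative disease risk by each age in [age_start, age_end].

    ``baseline`` and ``mortality`` are annual hazards for ages
    age_start … age_end−1 (length age_end − age_start).  Returns the risk
    trajectory A over ages age_start … age_end (length n_years + 1, starting
    at 0).
    """
    baseline = np.asarray(baseline, float)
    mortality = np.asarray(mortality, float)
    n_years = age_end - age_start
    if len(baseline) < n_years or len(mortality) < n_years:
        raise ValueError("hazard arrays shorter than the requested age span")
    h = baseline[:n_years] * rr_k
    mu = mortality[:n_years]
    if np.any(h < 0) or np.any(mu < 0):
        raise ValueError("negative hazards")
    total = h + mu
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, h / np.where(total > 0, total, 1.0), 0.0)
    step = frac * (1.0 - np.exp(-total))
    surv = np.concatenate([[1.0], np.cumprod(np.exp(-total))])
    A = np.concatenate([[0.0], np.cumsum(surv[:-1] * step)])
    return A


def event_free_survival(baseline: np.ndarray, rr_k: float,
                        mortality: np.ndarray, age_start: int,
                        age_end: int) -> np.ndarray:
    """S(t): probability alive and disease-free at each age of the grid."""
    h = np.asarray(baseline, float)[:age_end - age_start] * rr_k
    mu = np.asarray(mortality, float)[:age_end - age_start]
    return np.concatenate([[1.0], np.cumprod(np.exp(-(h + mu)))])


def ten_year_risk(baseline: np.ndarray, rr_k: float, mortality: np.ndarray,
                  age: int, age_start: int = DEFAULT_AGE_START,
                  age_end: int = DEFAULT_AGE_END) -> float:
    """Conditional 10-year risk at ``age``, given alive and disease-free.

    Restarts the cumulative-risk recursion at ``age`` with S = 1; requires
    ``age`` and ``age + 10`` to lie inside the hazard grid.
    """
    if age < age_start or age + 10 > age_end:
        raise ValueError(
            f"10-year window [{age}, {age + 10}] outside hazard grid "
            f"[{age_start}, {age_end}]"
        )
    lo = age - age_start
    A = cumulative_risk(baseline[lo:lo + 10], rr_k, mortality[lo:lo + 10],
                        age_start=age, age_end=age + 10)
    return float(A[-1])


def risk_curves(rates: RateTable, rr: np.ndarray, p_bin: np.ndarray,
                categories: list[str] | None = None,
                age_start: int = DEFAULT_AGE_START,
                age_end: int = DEFAULT_AGE_END) -> RiskCurve:
    """Cumulative-risk trajectories for a full set of categories."""
    rr = np.asarray(rr, float)
    p_bin = np.asarray(p_bin, float)
    lam = rates.incidence_on(age_start, age_end - 1)
    mu = rates.mortality_on(age_start, age_end - 1)
    lam0 = constrain_baseline(lam, rr, p_bin)
    ages = np.arange(age_start, age_end + 1)
    cum = np.vstack([cumulative_risk(lam0, r, mu, age_start, age_end) for r in rr])
    if categories is None:
        categories = [f"cat{k}" for k in range(len(rr))]
    return RiskCurve(list(categories), rr, p_bin, ages, cum)


def screening_threshold(rates: RateTable, age: int = 47) -> float:
    """Population-average 10-year risk at ``age`` (default 47), the screening-
    eligibility threshold; computed from the supplied rates, never hard-coded."""
    lam = rates.incidence_on(age, age + 9)
    mu = rates.mortality_on(age, age + 9)
    return ten_year_risk(lam, 1.0, mu, age, age_start=age, age_end=age + 10)


def age_at_threshold(baseline: np.ndarray, rr_k: float, mortality: np.ndarray,
                     threshold: float, age_start: int = DEFAULT_AGE_START,
                     age_end: int = DEFAULT_AGE_END) -> int | None:
    """Smallest integer age at which the category's conditional 10-year risk
    reaches ``threshold``, or None if it never does within the grid."""
    for age in range(age_start, age_end - 10 + 1):
        if ten_year_risk(baseline, rr_k, mortality, age, age_start, age_end) >= threshold:
            return age
    return None


# ---------------------------------------------------------------------------
# ER-subtype and family-history stratified risks
# ---------------------------------------------------------------------------

def subtype_risks(rates: RateTable, rr_erpos: np.ndarray, p_bin_erpos: np.ndarray,
                  rr_erneg: np.ndarray, p_bin_erneg: np.ndarray,
                  age_start: int = DEFAULT_AGE_START,
                  age_end: int = DEFAULT_AGE_END) -> dict:
    """Joint ER-positive / ER-negative absolute risks.

    Population incidence is split by the ER-positive proportion,
    λ+(t) = π+(t)·λ(t) and λ−(t) = (1−π+(t))·λ(t); each subtype baseline is
    constrained with its own relative-risk set; the joint survival of a woman
    in ER+ bin i and ER− bin j removes her through both subtype hazards and
    competing mortality, while each subtype's risk accrues from its own
    hazard.  Marginal subtype risks average the joint grid over the other
    subtype's bin fractions.
    """
    lam = rates.incidence_on(age_start, age_end - 1)
    mu = rates.mortality_on(age_start, age_end - 1)
    pi = rates.er_pos_prop_on(age_start, age_end - 1)
    lam_pos = pi * lam
    lam_neg = (1.0 - pi) * lam
    rr_erpos = np.asarray(rr_erpos, float)
    rr_erneg = np.asarray(rr_erneg, float)
    p_pos = np.asarray(p_bin_erpos, float)
    p_neg = np.asarray(p_bin_erneg, float)
    lam0_pos = constrain_baseline(lam_pos, rr_erpos, p_pos)
    lam0_neg = constrain_baseline(lam_neg, rr_erneg, p_neg)

    n_pos, n_neg = len(rr_erpos), len(rr_erneg)
    n_years = age_end - age_start
    ages = np.arange(age_start, age_end + 1)
    cum_pos = np.zeros((n_pos, n_neg, n_years + 1))
    cum_neg = np.zeros((n_pos, n_neg, n_years + 1))
    for i in range(n_pos):
        h_pos = lam0_pos * rr_erpos[i]
        for j in range(n_neg):
            h_neg = lam0_neg * rr_erneg[j]
            total = h_pos + h_neg + mu
            with np.errstate(invalid="ignore", divide="ignore"):
                safe = np.where(total > 0, total, 1.0)
                step = 1.0 - np.exp(-total)
                acc_pos = np.where(total > 0, h_pos / safe, 0.0) * step
                acc_neg = np.where(total > 0, h_neg / safe, 0.0) * step
            surv = np.concatenate([[1.0], np.cumprod(np.exp(-total))])
            cum_pos[i, j] = np.concatenate([[0.0], np.cumsum(surv[:-1] * acc_pos)])
            cum_neg[i, j] = np.concatenate([[0.0], np.cumsum(surv[:-1] * acc_neg)])

    # marginal over the other subtype's bin fractions
    marg_pos = np.tensordot(cum_pos, p_neg, axes=([1], [0]))
    marg_neg = np.tensordot(np.moveaxis(cum_neg, 0, 1), p_pos, axes=([1], [0]))
    return {
        "ages": ages,
        "joint_erpos": cum_pos,
        "joint_erneg": cum_neg,
        "marginal_erpos": marg_pos,
        "marginal_erneg": marg_neg,
    }


def fh_stratified_risks(rates: RateTable, rr: np.ndarray, p_bin: np.ndarray,
                        fh_or: float, fh_prevalence: float,
                        age_start: int = DEFAULT_AGE_START,
                        age_end: int = DEFAULT_AGE_END) -> dict[str, RiskCurve]:
    """Absolute risks by PRS bin within family-history strata.

    Joint categories are bins × {FH, no FH} with multiplicative relative
    risks (bin rr × fh_or in the FH stratum) and fractions
    p_bin × (prevalence, 1 − prevalence); the baseline is re-constrained over
    the joint set so the population incidence is still reproduced.
    """
    if fh_or <= 0:
        raise ValueError("fh_or must be positive")
    if not (0.0 < fh_prevalence < 1.0):
        raise ValueError("fh_prevalence must lie in (0, 1)")
    rr = np.asarray(rr, float)
    p_bin = np.asarray(p_bin, float)
    lam = rates.incidence_on(age_start, age_end - 1)
    mu = rates.mortality_on(age_start, age_end - 1)
    joint_rr = np.concatenate([rr * fh_or, rr])
    joint_p = np.concatenate([p_bin * fh_prevalence, p_bin * (1 - fh_prevalence)])
    lam0 = constrain_baseline(lam, joint_rr, joint_p)
    ages = np.arange(age_start, age_end + 1)
    out: dict[str, RiskCurve] = {}
    for name, rr_set, p_set in (("fh", rr * fh_or, p_bin * fh_prevalence),
                                ("no_fh", rr, p_bin * (1 - fh_prevalence))):
        cum = np.vstack([cumulative_risk(lam0, r, mu, age_start, age_end)
                         for r in rr_set])
        out[name] = RiskCurve([f"bin{k}" for k in range(len(rr))],
                              rr_set, p_set / p_set.sum(), ages, cum)
    return out


def risk_ci(log_rr: np.ndarray, cov: np.ndarray, rates: RateTable,
            p_bin: np.ndarray, n_draws: int = 2000, seed: int = 0,
            age_start: int = DEFAULT_AGE_START,
            age_end: int = DEFAULT_AGE_END,
            alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo confidence bands for per-category cumulative risks.

    Draws log relative-risk vectors from MVN(log_rr, cov), re-constrains the
    baseline and recomputes the risk trajectories for each draw, and reports
    the α/2 and 1−α/2 pointwise percentiles.  Deterministic under a fixed
    seed; a non-positive-semi-definite covariance is a hard error.
    """
    log_rr = np.asarray(log_rr, float)
    cov = np.atleast_2d(np.asarray(cov, float))
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    lam = rates.incidence_on(age_start, age_end - 1)
    mu = rates.mortality_on(age_start, age_end - 1)
    n_cat = len(log_rr)
    n_ages = age_end - age_start + 1
    draws = rng.multivariate_normal(log_rr, cov, size=n_draws,
                                    method="svd")  # svd tolerates PSD-singular cov
    curves = np.empty((n_draws, n_cat, n_ages))
    for d in range(n_draws):
        rr_d = np.exp(draws[d])
        lam0 = constrain_baseline(lam, rr_d, p_bin)
        for k in range(n_cat):
            curves[d, k] = cumulative_risk(lam0, rr_d[k], mu, age_start, age_end)
    lo = np.percentile(curves, 100 * alpha / 2, axis=0)
    hi = np.percentile(curves, 100 * (1 - alpha / 2), axis=0)
    return lo, hi
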