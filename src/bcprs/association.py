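"""Empirical case-control association fits for the polygenic risk score.

Logistic-regression estimates adjusted for study and seven principal
components: odds ratios by percentile bin of the PRS (middle quintile as
reference), the per-SD effect with an optional PRS×age interaction, the
attenuation of the family-history OR after PRS adjustment, the joint
PRS × family-history model, and the C-statistic with a DeLong asymptotic CI.

ER-subtype endpoints fit cases of that subtype against all controls using the
subtype-specific score, the standard case-control subtype analysis.  All
tests are two-sided Wald.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .data_model_io import CohortTable, PercentileScheme
from .prs_core import _design_matrix

logger = logging.getLogger("bcprs")

Z95 = norm.ppf(0.975)


class FitError(RuntimeError):
    """Logistic fit failed to converge (diagnostics in the message)."""


def _covariate_design(cohort: CohortTable, rows: np.ndarray) -> np.ndarray:
    """Intercept + indicator-coded study + 7 PCs for the selected rows."""
    frame = cohort.covariate_frame().loc[rows].reset_index(drop=True)
    return _design_matrix(frame, n=len(frame))


def _fit_logit(y: np.ndarray, X: np.ndarray, context: str):
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singularities
        raise FitError(f"logistic fit failed for {context}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"logistic fit did not converge for {context} "
                       f"(n={len(y)}, p={X.shape[1]})")
    return res


@dataclass
class PerSDFit:
    """Per-SD log OR and, optionally, the PRS×age interaction OR per decade."""

    log_or: float
    se: float
    ci: tuple[float, float]
    p: float
    age_or_per10: float | None = None
    age_or_ci: tuple[float, float] | None = None
    age_p: float | None = None


def _endpoint_rows(cohort: CohortTable, endpoint: str) -> np.ndarray:
    """Row mask: all controls plus cases of the requested endpoint."""
    status = cohort.status
    if endpoint == "overall":
        return np.ones(cohort.n, bool)
    if endpoint in ("erpos", "erneg"):
        want = "pos" if endpoint == "erpos" else "neg"
        er = cohort.df["er_status"].to_numpy()
        return (status == 0) | ((status == 1) & (er == want))
    raise ValueError(f"unknown endpoint {endpoint!r}")


def fit_bin_ors(cohort: CohortTable, bin_labels: np.ndarray,
                scheme: PercentileScheme | None = None,
                endpoint: str = "overall",
                adjust: bool = True) -> pd.DataFrame:
    """ORs for breast cancer by percentile bin, middle quintile as reference.

    Logistic status ~ bin indicators + study + PCs; bins lacking a case or a
    control are flagged (OR omitted) and their individuals excluded from the
    fit.  Returns one row per bin with OR, Wald 95% CI, P and counts.
    """
    scheme = scheme or PercentileScheme()
    bin_labels = np.asarray(bin_labels, object)
    keep = _endpoint_rows(cohort, endpoint) & np.array([b is not None
                                                        for b in bin_labels])
    status = cohort.status
    counts = {lab: (int(((bin_labels == lab) & keep & (status == 1)).sum()),
                    int(((bin_labels == lab) & keep & (status == 0)).sum()))
              for lab in scheme.labels}
    usable = [lab for lab in scheme.labels
              if lab == scheme.reference_label or
              (counts[lab][0] >= 1 and counts[lab][1] >= 1)]
    flagged = [lab for lab in scheme.labels if lab not in usable]
    if flagged:
        logger.warning("bins without both cases and controls flagged: %s", flagged)
    keep &= np.isin(bin_labels, usable)
    rows = np.flatnonzero(keep)
    y = status[rows]
    non_ref = [lab for lab in usable if lab != scheme.reference_label]
    dummies = np.column_stack([(bin_labels[rows] == lab).astype(float)
                               for lab in non_ref]) if non_ref else np.empty((len(rows), 0))
    X = np.column_stack([dummies, _covariate_design(cohort, rows)]) if adjust else \
        np.column_stack([dummies, np.ones(len(rows))])
    res = _fit_logit(y, X, f"bin ORs ({endpoint})")
    out = []
    for lab in scheme.labels:
        n_ca, n_co = counts[lab]
        if lab == scheme.reference_label:
            out.append((lab, n_ca, n_co, 1.0, np.nan, np.nan, np.nan))
        elif lab in usable:
            j = non_ref.index(lab)
            b, se = res.params[j], res.bse[j]
            out.append((lab, n_ca, n_co, float(np.exp(b)),
                        float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)),
                        float(res.pvalues[j])))
        else:
            out.append((lab, n_ca, n_co, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(out, columns=["bin", "n_cases", "n_controls", "or",
                                      "ci_low", "ci_high", "p"])


def fit_per_sd(cohort: CohortTable, scores: np.ndarray,
               endpoint: str = "overall", age_interaction: bool = False,
               adjust: bool = True) -> PerSDFit:
    """Per-SD log OR of the score; optionally the interaction OR per decade.

    Scores are standardised to control SD 1 before fitting.  With
    ``age_interaction`` the design adds (age−50)/10 and score×(age−50)/10;
    exp of the product-term coefficient is reported as the OR per 10 years.
    The age main effect is included alongside the product term so the
    interaction estimate is not absorbed by an age gradient in case
    probability.
    """
    scores = np.asarray(scores, float)
    rows = np.flatnonzero(_endpoint_rows(cohort, endpoint) & ~np.isnan(scores))
    status = cohort.status[rows]
    control_sd = scores[rows][status == 0].std(ddof=1)
    if not np.isfinite(control_sd) or control_sd == 0:
        raise ValueError("scores have no variance among controls")
    z = (scores[rows] - scores[rows][status == 0].mean()) / control_sd
    cols = [z]
    names = ["per_sd"]
    if age_interaction:
        decades = (cohort.df["age"].to_numpy(float)[rows] - 50.0) / 10.0
        cols += [decades, z * decades]
        names += ["age", "per_sd_x_age"]
    X = np.column_stack(cols + [_covariate_design(cohort, rows) if adjust
                                else np.ones((len(rows), 1))])
    res = _fit_logit(status, X, f"per-SD fit ({endpoint})")
    b, se = float(res.params[0]), float(res.bse[0])
    fit = PerSDFit(b, se, (b - Z95 * se, b + Z95 * se), float(res.pvalues[0]))
    if age_interaction:
        j = names.index("per_sd_x_age")
        bi, sei = float(res.params[j]), float(res.bse[j])
        fit.age_or_per10 = float(np.exp(bi))
        fit.age_or_ci = (float(np.exp(bi - Z95 * sei)), float(np.exp(bi + Z95 * sei)))
        fit.age_p = float(res.pvalues[j])
    return fit


def attenuation_pct(or_unadjusted: float, or_adjusted: float) -> float:
    """Percent attenuation of a log OR after adjustment:
    100·(ln ORu − ln ORa)/ln ORu.  Undefined (error) when ORu ≤ 1."""
    if or_unadjusted <= 1.0:
        raise ValueError("attenuation undefined for an unadjusted OR ≤ 1")
    return 100.0 * (np.log(or_unadjusted) - np.log(or_adjusted)) / np.log(or_unadjusted)


DEFAULT_AGE_STRATA = (("all", 0.0, np.inf), ("<40", 0.0, 40.0),
                      ("40-60", 40.0, 60.0), (">=60", 60.0, np.inf))


def family_history_attenuation(cohort: CohortTable, scores: np.ndarray,
                               age_strata=DEFAULT_AGE_STRATA) -> pd.DataFrame:
    """FH odds ratio before/after PRS adjustment, overall and by age stratum.

    Unadjusted: logistic status ~ FH + study + PCs; adjusted adds the
    standardised continuous PRS.  Percent attenuation is on the log scale;
    strata where the unadjusted OR ≤ 1 are flagged with NaN attenuation.
    """
    scores = np.asarray(scores, float)
    fh = cohort.df["family_history"].to_numpy(float)
    age = cohort.df["age"].to_numpy(float)
    status = cohort.status
    base = ~np.isnan(fh) & ~np.isnan(scores)
    if not base.any():
        raise ValueError("no rows with observed family history")
    control_sd = scores[base][status[base] == 0].std(ddof=1)
    z_all = scores / control_sd
    rows_out = []
    for name, lo, hi in age_strata:
        mask = base & (age >= lo) & (age < hi)
        rows = np.flatnonzero(mask)
        if len(rows) == 0 or len(np.unique(status[rows])) < 2:
            rows_out.append((name, len(rows), np.nan, np.nan, np.nan))
            continue
        cov = _covariate_design(cohort, rows)
        Xu = np.column_stack([fh[rows], cov])
        Xa = np.column_stack([fh[rows], z_all[rows], cov])
        try:
            oru = float(np.exp(_fit_logit(status[rows], Xu,
                                          f"FH unadjusted {name}").params[0]))
            ora = float(np.exp(_fit_logit(status[rows], Xa,
                                          f"FH adjusted {name}").params[0]))
        except FitError as exc:  # sparse stratum: flag, don't abort
            logger.warning("stratum %s flagged: %s", name, exc)
            rows_out.append((name, len(rows), np.nan, np.nan, np.nan))
            continue
        att = attenuation_pct(oru, ora) if oru > 1.0 else np.nan
        if oru <= 1.0:
            logger.warning("stratum %s: unadjusted FH OR ≤ 1, attenuation undefined",
                           name)
        rows_out.append((name, len(rows), oru, ora, att))
    return pd.DataFrame(rows_out, columns=["stratum", "n", "or_unadjusted",
                                           "or_adjusted", "pct_attenuation"])


def c_statistic(scores: np.ndarray, status: np.ndarray,
                ) -> tuple[float, tuple[float, float]]:
    """AUC (Mann–Whitney with midrank ties) and DeLong asymptotic 95% CI."""
    scores = np.asarray(scores, float)
    status = np.asarray(status, int)
    ok = ~np.isnan(scores)
    x = scores[ok & (status == 1)]
    y = scores[ok & (status == 0)]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both cases and controls are required")
    ranks = rankdata(np.concatenate([x, y]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks[:m] - rankdata(x)) / n           # placement of each case
    v01 = 1.0 - (ranks[m:] - rankdata(y)) / m     # placement of each control
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + \
          (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    return float(auc), (float(auc - Z95 * se), float(auc + Z95 * se))


def fh_by_prs_joint(cohort: CohortTable, scores: np.ndarray,
                    bin_labels: np.ndarray | None = None,
                    scheme: PercentileScheme | None = None) -> dict:
    """Joint FH × PRS model: multiplicative-interaction test plus per-bin FH ORs.

    Logistic status ~ FH + standardised PRS + FH×PRS + study + PCs; the Wald
    P for the product term tests departure from multiplicative joint effects.
    When bin labels are supplied, FH ORs within each PRS bin are reported for
    inspection (sparse bins flagged with NaN).
    """
    scores = np.asarray(scores, float)
    fh = cohort.df["family_history"].to_numpy(float)
    status = cohort.status
    base = ~np.isnan(fh) & ~np.isnan(scores)
    if not base.any():
        raise ValueError("no rows with observed family history")
    if np.all(fh[base] == 0) or np.all(fh[base] == 1):
        raise ValueError("family history has no variation")
    rows = np.flatnonzero(base)
    control_sd = scores[rows][status[rows] == 0].std(ddof=1)
    z = (scores[rows] - scores[rows][status[rows] == 0].mean()) / control_sd
    X = np.column_stack([fh[rows], z, fh[rows] * z, _covariate_design(cohort, rows)])
    res = _fit_logit(status[rows], X, "FH x PRS joint model")
    out = {
        "fh_log_or": float(res.params[0]),
        "per_sd_log_or": float(res.params[1]),
        "interaction_log_or": float(res.params[2]),
        "interaction_se": float(res.bse[2]),
        "interaction_p": float(res.pvalues[2]),
    }
    if bin_labels is not None:
        scheme = scheme or PercentileScheme()
        bin_labels = np.asarray(bin_labels, object)
        per_bin = []
        for lab in scheme.labels:
            sel = np.flatnonzero(base & (bin_labels == lab))
            n_tab = pd.crosstab(status[sel], fh[sel]) if len(sel) else None
            if n_tab is None or n_tab.shape != (2, 2) or (n_tab.values == 0).any():
                per_bin.append((lab, len(sel), np.nan, np.nan, np.nan))
                continue
            Xb = np.column_stack([fh[sel], _covariate_design(cohort, sel)])
            try:
                rb = _fit_logit(status[sel], Xb, f"FH OR in bin {lab}")
                b, se = rb.params[0], rb.bse[0]
                per_bin.append((lab, len(sel), float(np.exp(b)),
                                float(np.exp(b - Z95 * se)),
                                float(np.exp(b + Z95 * se))))
            except FitError:
                per_bin.append((lab, len(sel), np.nan, np.nan, np.nan))
        out["fh_or_by_bin"] = pd.DataFrame(
            per_bin, columns=["bin", "n", "fh_or", "ci_low", "ci_high"])
    return out
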