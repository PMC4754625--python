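"""All-pairs SNP×SNP multiplicative-interaction scan.

Case-control test: logistic regression of status on study + PCs, each SNP
coded categorically (separate heterozygote and risk-homozygote parameters),
plus the dose_a×dose_b product as a continuous covariate; the 1-df Wald test
on the product coefficient detects departure from the multiplicative
(log-additive) model.  Doses are coded on the risk-allele orientation.

Case-only test: within cases, linear regression of one SNP's dose on the
other's (plus covariates); under population independence of the loci,
association among cases indicates interaction.  The same regression run
within controls is the screen that protects case-only validity — pairs
correlated among controls (P ≤ α) are excluded from the case-only counts.

The scan summary counts pairs significant at α, compares with the expected
count n·α under a Poisson null (two-sided), and tests whether synergistic
(positive product coefficient under risk coding) and antagonistic directions
are balanced.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import binomtest, poisson

from .association import FitError, _covariate_design, _fit_logit
from .data_model_io import CohortTable, GenotypeMatrix, SNPPanel

logger = logging.getLogger("bcprs")


@dataclass
class InteractionResult:
    """One SNP pair's interaction estimate and P values."""

    snp_a: str
    snp_b: str
    gamma: float = np.nan        # product-term log OR (case-control mode)
    se: float = np.nan
    p_cc: float = np.nan
    p_co: float = np.nan         # case-only
    p_controls: float = np.nan   # control-only screen
    direction: str = "undefined"  # synergistic | antagonistic | undefined
    converged: bool = True


@dataclass
class ScanSummary:
    """Observed vs expected significant pairs with Poisson and sign tests."""

    n_pairs: int
    n_observed: int
    expected: float
    ratio: float
    poisson_p: float
    n_synergistic: int = 0
    n_antagonistic: int = 0
    frac_synergistic: float = np.nan
    binomial_p: float = np.nan

    @property
    def ratio_2dp(self) -> float:
        """Ratio rounded to 2 decimals, the display convention."""
        return round(self.ratio, 2)


def all_pair_ids(snp_ids: list[str]) -> list[tuple[str, str]]:
    """All unordered SNP pairs, n·(n−1)/2 of them, in panel order."""
    return list(itertools.combinations(snp_ids, 2))


def _risk_oriented(genotypes: GenotypeMatrix, panel: SNPPanel, j: int) -> np.ndarray:
    """Dosage column recoded so the per-allele overall log OR is ≥ 0."""
    d = genotypes.dosages[:, j]
    return 2.0 - d if panel.betas("overall")[j] < 0 else d.copy()


def _pair_data(genotypes: GenotypeMatrix, cohort: CohortTable, panel: SNPPanel,
               snp_a: str, snp_b: str):
    ja = panel.snp_ids.index(snp_a)
    jb = panel.snp_ids.index(snp_b)
    da = _risk_oriented(genotypes, panel, ja)
    db = _risk_oriented(genotypes, panel, jb)
    ok = ~np.isnan(da) & ~np.isnan(db)
    for name, d in ((snp_a, da[ok]), (snp_b, db[ok])):
        if len(np.unique(d)) < 2:
            raise ValueError(f"SNP {name} has a single observed genotype class")
    return da, db, ok


def test_pair_cc(genotypes: GenotypeMatrix, cohort: CohortTable,
                 panel: SNPPanel, snp_a: str, snp_b: str,
                 adjust: bool = True) -> InteractionResult:
    """Case-control interaction test for one SNP pair (1-df Wald on the
    continuous product term; SNP main effects coded categorically)."""
    da, db, ok = _pair_data(genotypes, cohort, panel, snp_a, snp_b)
    rows = np.flatnonzero(ok)
    y = cohort.status[rows]
    a, b = da[rows], db[rows]
    X = np.column_stack([
        (a == 1).astype(float), (a == 2).astype(float),
        (b == 1).astype(float), (b == 2).astype(float),
        a * b,
        _covariate_design(cohort, rows) if adjust else np.ones(len(rows)),
    ])
    result = InteractionResult(snp_a, snp_b)
    try:
        res = _fit_logit(y, X, f"interaction {snp_a}*{snp_b}")
    except FitError as exc:
        logger.warning("%s", exc)
        result.converged = False
        return result
    result.gamma = float(res.params[4])
    result.se = float(res.bse[4])
    result.p_cc = float(res.pvalues[4])
    beta_a = panel.betas("overall")[panel.snp_ids.index(snp_a)]
    beta_b = panel.betas("overall")[panel.snp_ids.index(snp_b)]
    if result.gamma == 0.0 or beta_a == 0.0 or beta_b == 0.0:
        result.direction = "undefined"
    else:
        result.direction = "synergistic" if result.gamma > 0 else "antagonistic"
    return result


def test_pair_stratum(genotypes: GenotypeMatrix, cohort: CohortTable,
                      panel: SNPPanel, snp_a: str, snp_b: str,
                      stratum: str = "cases",
                      adjust: bool = True) -> tuple[float, float]:
    """Case-only (or control-only) test: within the stratum, linear regression
    of dose_a on dose_b + covariates; returns (slope, two-sided P)."""
    da, db, ok = _pair_data(genotypes, cohort, panel, snp_a, snp_b)
    want = 1 if stratum == "cases" else 0
    if stratum not in ("cases", "controls"):
        raise ValueError(f"stratum must be 'cases' or 'controls', got {stratum!r}")
    rows = np.flatnonzero(ok & (cohort.status == want))
    if len(rows) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    X = np.column_stack([db[rows],
                         _covariate_design(cohort, rows) if adjust
                         else np.ones(len(rows))])
    res = sm.OLS(da[rows], X).fit()
    return float(res.params[0]), float(res.pvalues[0])


def _main_effect_p(genotypes: GenotypeMatrix, cohort: CohortTable,
                   panel: SNPPanel, j: int, adjust: bool) -> float:
    """Per-allele main-effect Wald P for one SNP (used to pick the linked-
    group representative)."""
    d = genotypes.dosages[:, j]
    rows = np.flatnonzero(~np.isnan(d))
    X = np.column_stack([d[rows],
                         _covariate_design(cohort, rows) if adjust
                         else np.ones(len(rows))])
    try:
        res = _fit_logit(cohort.status[rows], X, f"main effect {panel.snp_ids[j]}")
        return float(res.pvalues[0])
    except FitError:
        return 1.0


def select_unlinked(genotypes: GenotypeMatrix, cohort: CohortTable,
                    panel: SNPPanel, adjust: bool = True) -> list[str]:
    """One SNP per region_id: the one with the smallest main-effect P in this
    dataset.  Pairs within a region are thereby never tested."""
    best: dict[str, tuple[float, str]] = {}
    for j, sid in enumerate(panel.snp_ids):
        region = panel.df["region_id"].iloc[j]
        p = _main_effect_p(genotypes, cohort, panel, j, adjust)
        if region not in best or p < best[region][0]:
            best[region] = (p, sid)
    chosen = {sid for _, sid in best.values()}
    return [sid for sid in panel.snp_ids if sid in chosen]  # panel order


def scan_all_pairs(genotypes: GenotypeMatrix, cohort: CohortTable,
                   panel: SNPPanel, alpha: float = 0.01, mode: str = "cc",
                   unlinked_only: bool = False, adjust: bool = True,
                   ) -> tuple[list[InteractionResult], ScanSummary]:
    """Scan every unordered SNP pair and summarise the excess of significant
    interactions.

    ``mode='cc'`` runs the case-control product-term test; ``'caseonly'``
    runs the case-only dose-on-dose test with the control-only screen (pairs
    with control-only P ≤ α are excluded from the counts).  With
    ``unlinked_only`` the scan keeps one representative SNP per region.
    Non-converged fits are dropped from both numerator and denominator.
    """
    if mode not in ("cc", "caseonly"):
        raise ValueError(f"mode must be 'cc' or 'caseonly', got {mode!r}")
    snps = (select_unlinked(genotypes, cohort, panel, adjust)
            if unlinked_only else list(panel.snp_ids))
    results: list[InteractionResult] = []
    n_dropped = 0
    for snp_a, snp_b in all_pair_ids(snps):
        if mode == "cc":
            r = test_pair_cc(genotypes, cohort, panel, snp_a, snp_b, adjust)
            if not r.converged:
                n_dropped += 1
            results.append(r)
        else:
            r = InteractionResult(snp_a, snp_b)
            try:
                slope, r.p_co = test_pair_stratum(genotypes, cohort, panel,
                                                  snp_a, snp_b, "cases", adjust)
                _, r.p_controls = test_pair_stratum(genotypes, cohort, panel,
                                                    snp_a, snp_b, "controls", adjust)
            except ValueError:
                r.converged = False
                n_dropped += 1
                results.append(r)
                continue
            r.gamma = slope
            beta_a = panel.betas("overall")[panel.snp_ids.index(snp_a)]
            beta_b = panel.betas("overall")[panel.snp_ids.index(snp_b)]
            if slope == 0.0 or beta_a == 0.0 or beta_b == 0.0:
                r.direction = "undefined"
            else:
                r.direction = "synergistic" if slope > 0 else "antagonistic"
            results.append(r)
    if n_dropped:
        logger.warning("%d pair(s) dropped (non-converged or empty stratum)",
                       n_dropped)
    countable = [r for r in results if r.converged]
    if mode == "caseonly":
        countable = [r for r in countable if r.p_controls > alpha]
    summary = summarize_scan(countable, alpha=alpha, mode=mode)
    return results, summary


def summarize_scan(results: list[InteractionResult], alpha: float = 0.01,
                   mode: str = "cc") -> ScanSummary:
    """Observed/expected significant pairs with a two-sided Poisson test.

    expected = α·n_pairs; poisson_p = min(1, 2·min(P(X ≤ obs), P(X ≥ obs)))
    for X ~ Poisson(expected).  The synergistic fraction among significant
    pairs is tested against 0.5 with a two-sided binomial test.
    """
    if len(results) == 0:
        raise ValueError("cannot summarise an empty scan")
    pvals = np.array([r.p_cc if mode == "cc" else r.p_co for r in results])
    sig = [r for r, p in zip(results, pvals) if np.isfinite(p) and p < alpha]
    summary = summary_from_counts(len(sig), len(results), alpha)
    n_syn = sum(1 for r in sig if r.direction == "synergistic")
    n_ant = sum(1 for r in sig if r.direction == "antagonistic")
    summary.n_synergistic = n_syn
    summary.n_antagonistic = n_ant
    if n_syn + n_ant > 0:
        summary.frac_synergistic = n_syn / (n_syn + n_ant)
        summary.binomial_p = float(binomtest(n_syn, n_syn + n_ant, 0.5).pvalue)
    return summary


def summary_from_counts(n_observed: int, n_pairs: int,
                        alpha: float = 0.01) -> ScanSummary:
    """Scan summary arithmetic from bare counts (no per-pair results needed)."""
    if n_pairs == 0:
        raise ValueError("n_pairs must be positive")
    expected = alpha * n_pairs
    ratio = n_observed / expected
    p = min(1.0, 2.0 * min(poisson.cdf(n_observed, expected),
                           poisson.sf(n_observed - 1, expected)))
    return ScanSummary(n_pairs=n_pairs, n_observed=n_observed,
                       expected=expected, ratio=float(ratio),
                       poisson_p=float(p))
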