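"""Synthetic case-control cohorts with the structure the analysis assumes.

Generates SNP weight panels, Hardy–Weinberg genotypes, retrospective
case-control phenotypes, family history and age-indexed rate tables so every
downstream stage runs without any external download.

Disease model
-------------
Individuals carry a polygenic score s = Σ β_k x_k and a residual polygenic
liability u, with relative risk ∝ exp(s + u).  Case genotypes are drawn by
exponential tilting — for relative risk e^{βx} the case genotype distribution
is HWE(p) reweighted by e^{βx} per SNP — which is the exact retrospective
distribution under the multiplicative (log-additive) model with independent
loci, and avoids rejection sampling from a large population pool entirely.

The per-SD log OR at age a decays additively in the fitted-model coefficient:
per-SD(a) = σ + ln(age_interaction_per10)·(a−50)/10, so a logistic fit with a
score×(age−50)/10 product term recovers ``age_interaction_per10`` as the
interaction OR per decade.

The latent total liability G (of which the PRS is a component) has variance
σ_T² = 2·ln(fh_frr), so the implied first-degree familial relative risk
exp(σ_T²/2) equals ``fh_frr``.  Each individual gets one first-degree
relative with liability correlation 0.5; family history is that relative's
lifetime affection status.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import absolute_risk
from .data_model_io import (CohortTable, GenotypeMatrix, RateTable, SNPPanel,
                            PANEL_COLUMNS, PC_COLUMNS)
from .polygenic_model import theoretical_sd

logger = logging.getLogger("bcprs")


def substream_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the analysis conditions: a 77-SNP panel whose score SD
    is 0.45 overall (0.50 ER-positive, 0.38 ER-negative), a two-fold
    first-degree familial relative risk, an interaction OR of 0.98 per decade
    of age, and 78% of cases ER-positive.
    """

    n_snps: int = 77
    target_sd_overall: float = 0.45
    target_sd_erpos: float = 0.50
    target_sd_erneg: float = 0.38
    eaf_range: tuple[float, float] = (0.05, 0.95)
    endpoint_corr: float = 0.7
    snps_per_region: int = 1
    n_cases: int = 10_000
    n_controls: int = 10_000
    fh_frr: float = 2.0
    relative_lifetime_risk: float = 0.10
    age_interaction_per10: float = 0.98
    er_pos_case_fraction: float = 0.78
    age_mean: float = 56.0
    age_sd: float = 8.0
    age_limits: tuple[float, float] = (25.0, 79.0)
    n_studies: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be non-negative")
        for name in ("target_sd_overall", "target_sd_erpos", "target_sd_erneg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.fh_frr < 1:
            raise ValueError("fh_frr must be at least 1")
        if not (0.0 <= self.er_pos_case_fraction <= 1.0):
            raise ValueError("er_pos_case_fraction must lie in [0, 1]")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")
        if not (-1.0 <= self.endpoint_corr <= 1.0):
            raise ValueError("endpoint_corr must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T"),
                 ("A", "T"), ("C", "G")]


def make_panel(config: SimulationConfig,
               rng: np.random.Generator | None = None) -> SNPPanel:
    """Draw a weight panel whose theoretical score SD hits the targets exactly.

    Effect-allele frequencies are uniform on ``eaf_range``; per-allele log ORs
    for the three endpoints are drawn jointly normal with pairwise correlation
    ``endpoint_corr``, oriented so the effect allele is the risk allele for
    overall disease, then each endpoint column is rescaled by one
    multiplicative constant so sqrt(Σ 2·p(1−p)·β²) equals its target SD.
    """
    rng = rng or np.random.default_rng(substream_seed(config.seed, "panel"))
    k = config.n_snps
    eaf = rng.uniform(*config.eaf_range, size=k)
    corr = np.full((3, 3), config.endpoint_corr)
    np.fill_diagonal(corr, 1.0)
    raw = rng.multivariate_normal(np.zeros(3), corr, size=k)  # (k, 3)
    # orient per SNP: effect allele = risk allele for overall disease
    flip = np.where(raw[:, 0] < 0, -1.0, 1.0)
    raw *= flip[:, None]
    targets = (config.target_sd_overall, config.target_sd_erpos,
               config.target_sd_erneg)
    var_per_unit = 2.0 * eaf * (1.0 - eaf)
    betas = np.empty_like(raw)
    for j, target in enumerate(targets):
        norm = np.sqrt(np.sum(var_per_unit * raw[:, j] ** 2))
        betas[:, j] = raw[:, j] * (target / norm) if (target > 0 and norm > 0) else 0.0
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    records = pd.DataFrame({
        "snp_id": [f"rs{100000 + i}" for i in range(k)],
        "chrom": [str(1 + i % 22) for i in range(k)],
        "pos": np.arange(1, k + 1) * 1_000_000,
        "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "eaf": eaf,
        "beta_overall": betas[:, 0],
        "beta_erpos": betas[:, 1],
        "beta_erneg": betas[:, 2],
        "region_id": [f"region{i // config.snps_per_region}" for i in range(k)],
    })
    return SNPPanel(records[PANEL_COLUMNS])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _sample_genotypes(eaf: np.ndarray, tilt: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-SNP multinomial dosages with genotype weights HWE(p)·e^{tilt·x}.

    ``tilt`` has shape (n, k); tilt = 0 gives plain Hardy–Weinberg draws.
    """
    e1 = np.exp(tilt)
    w0 = np.broadcast_to((1.0 - eaf) ** 2, e1.shape)
    w1 = 2.0 * eaf * (1.0 - eaf) * e1
    w2 = eaf ** 2 * e1 ** 2
    total = w0 + w1 + w2
    c0 = w0 / total
    c1 = c0 + w1 / total
    u = rng.random(e1.shape)
    return (u > c0).astype(float) + (u > c1)


def simulate_genotypes(panel: SNPPanel, n: int,
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: i.i.d. dosages with P(0)=(1−p)², P(1)=2p(1−p),
    P(2)=p² per SNP, SNPs independent."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dos = _sample_genotypes(panel.eaf, np.zeros((n, panel.n_snps)), rng)
    ids = [f"ind{i:06d}" for i in range(n)]
    return GenotypeMatrix(ids, panel.snp_ids, dos)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _draw_ages(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    return np.clip(ages, *config.age_limits)


def simulate_cohort(panel: SNPPanel, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[GenotypeMatrix, CohortTable]:
    """Retrospective case-control sample under the multiplicative model.

    Controls are population (HWE) draws; case genotypes are exponentially
    tilted by the overall-endpoint weights, scaled per case so the per-SD log
    OR at age a is σ + ln(age_interaction_per10)·(a−50)/10.  ER subtype is
    assigned from the case's subtype-specific scores around the marginal
    ER-positive fraction.  Study labels and 7 PCs are inert nuisance
    covariates (no confounding).  The latent total liability is retained on
    the returned cohort for the family-history stage.
    """
    rng = rng or np.random.default_rng(substream_seed(config.seed, "cohort"))
    eaf = panel.eaf
    beta_o = panel.betas("overall")
    beta_pos = panel.betas("erpos")
    beta_neg = panel.betas("erneg")
    sigma_o = theoretical_sd(panel, "overall")
    sigma_pos = theoretical_sd(panel, "erpos")
    sigma_neg = theoretical_sd(panel, "erneg")
    mean_o = float(np.sum(2.0 * eaf * beta_o))
    mean_pos = float(np.sum(2.0 * eaf * beta_pos))
    mean_neg = float(np.sum(2.0 * eaf * beta_neg))

    n_ca, n_co = config.n_cases, config.n_controls
    ages_ca = _draw_ages(n_ca, config, rng)
    ages_co = _draw_ages(n_co, config, rng)

    # per-case tilt so per-SD log OR at age a is σ + ln(or10)·(a−50)/10
    decades = (ages_ca - 50.0) / 10.0
    if sigma_o > 0:
        scale = 1.0 + np.log(config.age_interaction_per10) * decades / sigma_o
        scale = np.maximum(scale, 0.0)
    else:
        scale = np.ones(n_ca)
    dos_ca = _sample_genotypes(eaf, scale[:, None] * beta_o, rng)
    dos_co = _sample_genotypes(eaf, np.zeros((n_co, panel.n_snps)), rng)

    # ER subtype from subtype-specific scores (centred, variance-normalised
    # weights keep the marginal close to er_pos_case_fraction)
    pi = config.er_pos_case_fraction
    z_pos = dos_ca @ beta_pos - mean_pos
    z_neg = dos_ca @ beta_neg - mean_neg
    log_w_pos = np.log(pi) + scale * z_pos - scale ** 2 * sigma_pos ** 2 / 2.0 \
        if pi > 0 else np.full(n_ca, -np.inf)
    log_w_neg = np.log(1 - pi) + scale * z_neg - scale ** 2 * sigma_neg ** 2 / 2.0 \
        if pi < 1 else np.full(n_ca, -np.inf)
    p_pos = 1.0 / (1.0 + np.exp(log_w_neg - log_w_pos))
    er_case = np.where(rng.random(n_ca) < p_pos, "pos", "neg")

    # latent total liability: PRS component + independent polygenic remainder
    sigma_t2 = 2.0 * np.log(config.fh_frr)
    z_o_ca = dos_ca @ beta_o - mean_o
    z_o_co = dos_co @ beta_o - mean_o
    if sigma_t2 >= sigma_o ** 2:
        sigma_u = float(np.sqrt(sigma_t2 - sigma_o ** 2))
        u_ca = rng.normal(sigma_u ** 2, sigma_u, n_ca) if sigma_u > 0 else np.zeros(n_ca)
        u_co = rng.normal(0.0, sigma_u, n_co) if sigma_u > 0 else np.zeros(n_co)
        g_ca, g_co = z_o_ca + u_ca, z_o_co + u_co
    else:
        warnings.warn("fh_frr below the familial risk implied by the PRS alone; "
                      "liability shrunk onto the PRS", stacklevel=2)
        shrink = np.sqrt(sigma_t2) / sigma_o if sigma_o > 0 else 0.0
        g_ca, g_co = shrink * z_o_ca, shrink * z_o_co

    n = n_ca + n_co
    ids = [f"case{i:06d}" for i in range(n_ca)] + [f"ctrl{i:06d}" for i in range(n_co)]
    dosages = np.vstack([dos_ca, dos_co])
    df = pd.DataFrame({
        "individual_id": ids,
        "status": np.concatenate([np.ones(n_ca, int), np.zeros(n_co, int)]),
        "age": np.concatenate([ages_ca, ages_co]),
        "er_status": np.concatenate([er_case, np.full(n_co, "unknown")]),
        "family_history": np.full(n, np.nan),
        "study_id": np.array([f"study{j + 1}" for j in
                              rng.integers(0, config.n_studies, size=n)]),
    })
    pcs = rng.standard_normal((n, 7))
    for j, col in enumerate(PC_COLUMNS):
        df[col] = pcs[:, j]
    cohort = CohortTable(df, liability=np.concatenate([g_ca, g_co]))
    genotypes = GenotypeMatrix(ids, panel.snp_ids, dosages)
    return genotypes, cohort


def simulate_family_history(cohort: CohortTable, config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> CohortTable:
    """Fill family_history from one simulated first-degree relative.

    The relative's liability G_r has correlation 0.5 with the individual's
    retained liability G (both Normal(0, σ_T²) in the population,
    σ_T² = 2·ln(fh_frr)); her lifetime affection probability is
    K·exp(G_r − σ_T²/2) with population lifetime risk K, capped at 1.
    """
    if cohort.liability is None:
        raise ValueError("cohort lacks the retained latent liability; generate "
                         "it with simulate_cohort")
    rng = rng or np.random.default_rng(substream_seed(config.seed, "family"))
    sigma_t2 = 2.0 * np.log(config.fh_frr)
    g = cohort.liability
    g_rel = 0.5 * g + np.sqrt(0.75 * sigma_t2) * rng.standard_normal(len(g))
    k_pop = config.relative_lifetime_risk
    p_aff = np.minimum(1.0, k_pop * np.exp(g_rel - sigma_t2 / 2.0))
    fh = (rng.random(len(g)) < p_aff).astype(float)
    df = cohort.df.copy()
    df["family_history"] = fh
    return CohortTable(df, liability=cohort.liability)


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------

def make_rate_table(target_lifetime_risk: float = 0.10,
                    ramp_midpoint: float = 52.0, ramp_width: float = 8.0,
                    gompertz_a: float = 2e-5, gompertz_b: float = 0.098,
                    er_pos_base: float = 0.70, er_pos_slope: float = 0.0016,
                    age_max: int = 100) -> RateTable:
    """Smooth synthetic rate table emulating national statistics.

    Incidence is zero before 20 and follows a logistic ramp in age whose
    plateau is calibrated (by root finding against the competing-risk engine)
    so the cumulative risk from 20 to 80 equals ``target_lifetime_risk``.
    Other-cause mortality is Gompertz a·e^{b·t}; the ER-positive proportion
    has a mild linear age trend around ~0.78 at midlife.
    """
    ages = np.arange(0, age_max + 1)
    shape = 1.0 / (1.0 + np.exp(-(ages - ramp_midpoint) / ramp_width))
    shape[ages < 20] = 0.0
    mortality = gompertz_a * np.exp(gompertz_b * ages)
    er_pos = np.clip(er_pos_base + er_pos_slope * ages, 0.0, 1.0)

    shape_span = shape[20:80]
    mu_span = mortality[20:80]

    def lifetime(plateau: float) -> float:
        return float(absolute_risk.cumulative_risk(plateau * shape_span, 1.0,
                                                   mu_span, 20, 80)[-1])

    if target_lifetime_risk > 0:
        plateau = brentq(lambda c: lifetime(c) - target_lifetime_risk,
                         1e-8, 1.0, xtol=1e-14)
    else:
        plateau = 0.0
    df = pd.DataFrame({"age": ages, "incidence": plateau * shape,
                       "mortality": mortality, "er_pos_prop": er_pos})
    return RateTable(df)
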