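"""Polygenic risk score computation, residualisation and percentile binning.

The score for individual i is the weighted allele count Σ_k β_k·x_ik, with
per-allele log ORs β_k from the weight panel and effect-allele dosages
x_ik ∈ {0, 1, 2}.  Scores are optionally residualised on study + principal
components (standardized Pearson residuals) and assigned to percentile bins
whose cutpoints come from the control score distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import GenotypeMatrix, PercentileScheme, SNPPanel

logger = logging.getLogger("bcprs")


@dataclass
class PRSResult:
    """Per-individual raw score, residual score and percentile bin label."""

    individual_ids: list[str]
    raw_score: np.ndarray
    residual_score: np.ndarray | None = None
    bin_label: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"individual_id": self.individual_ids,
                            "raw_score": self.raw_score})
        if self.residual_score is not None:
            out["residual_score"] = self.residual_score
        if self.bin_label is not None:
            out["bin_label"] = self.bin_label
        return out


def compute_prs(genotypes: GenotypeMatrix, panel: SNPPanel,
                endpoint: str = "overall",
                missing_policy: str = "mean_dose") -> np.ndarray:
    """Raw PRS = Σ_k β_k·x_ik for the chosen endpoint's weights.

    ``missing_policy='mean_dose'`` imputes a missing dosage with its
    Hardy–Weinberg expectation 2·eaf_k; ``'drop_individual'`` returns NaN for
    any individual with a missing dosage (flagged, not silently zeroed).
    """
    if list(genotypes.snp_ids) != list(panel.snp_ids):
        raise ValueError("genotype columns are not aligned to the panel order")
    beta = panel.betas(endpoint)
    x = genotypes.dosages
    if missing_policy == "mean_dose":
        x = np.where(np.isnan(x), 2.0 * panel.eaf, x)
        return x @ beta
    if missing_policy == "drop_individual":
        scores = np.where(np.isnan(x), 0.0, x) @ beta
        has_missing = np.isnan(genotypes.dosages).any(axis=1)
        scores[has_missing] = np.nan
        if has_missing.any():
            logger.warning("%d individual(s) dropped for missing dosages",
                           int(has_missing.sum()))
        return scores
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def residualize(scores: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Standardized Pearson residuals of the score regressed on covariates.

    Ordinary least squares of score on an intercept plus the covariates
    (categorical columns indicator-coded); the output is
    (score − fit) / SD(residuals), so it has mean 0 and SD 1.  Collinear
    design columns are dropped with a warning rather than failing.
    """
    scores = np.asarray(scores, float)
    X = _design_matrix(covariates, n=len(scores))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(f"rank-deficient covariate design ({rank} < {X.shape[1]}); "
                      "collinear columns dropped", stacklevel=2)
        # QR-based column selection keeps an independent subset
        _, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
        X = X[:, keep]
    coef, *_ = np.linalg.lstsq(X, scores, rcond=None)
    resid = scores - X @ coef
    sd = resid.std()  # population SD so the output SD is exactly 1
    if sd == 0:
        raise ValueError("scores are an exact linear function of the covariates")
    return resid / sd


def _design_matrix(covariates: pd.DataFrame, n: int) -> np.ndarray:
    if len(covariates) != n:
        raise ValueError("covariate rows do not align with scores")
    cols = [np.ones(n)]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def assign_percentiles(scores: np.ndarray, control_mask: np.ndarray,
                       scheme: PercentileScheme | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Assign every individual to a percentile bin of the control distribution.

    Cutpoints are empirical control quantiles (type-7 linear interpolation) at
    the scheme's interior boundaries; intervals are lower-open/upper-closed.
    Returns (bin labels per individual, cutpoints).
    """
    scheme = scheme or PercentileScheme()
    scores = np.asarray(scores, float)
    control_scores = scores[np.asarray(control_mask, bool)]
    control_scores = control_scores[~np.isnan(control_scores)]
    if len(control_scores) < scheme.n_bins:
        raise ValueError(
            f"{len(control_scores)} controls cannot define {scheme.n_bins} bins"
        )
    if len(control_scores) < 200:
        warnings.warn(f"only {len(control_scores)} controls; percentile "
                      "cutpoints will be unstable", stacklevel=2)
    interior = np.asarray(scheme.boundaries[1:-1], float)
    cutpoints = np.quantile(control_scores, interior, method="linear")
    if np.any(np.diff(cutpoints) <= 0):
        raise ValueError("degenerate control quantiles (tied cutpoints); "
                         "scores lack the spread to define the bins")
    # side='left': cutpoints[i-1] < s <= cutpoints[i] -> bin i
    idx = np.searchsorted(cutpoints, scores, side="left")
    labels = np.asarray(scheme.labels, object)[idx]
    labels[np.isnan(scores)] = None
    return labels, cutpoints


def score_pipeline(genotypes: GenotypeMatrix, panel: SNPPanel,
                   covariates: pd.DataFrame | None = None,
                   control_mask: np.ndarray | None = None,
                   endpoint: str = "overall",
                   missing_policy: str = "mean_dose",
                   scheme: PercentileScheme | None = None,
                   bin_on: str = "raw") -> PRSResult:
    """Convenience wrapper: score, residualise, and bin in one call.

    ``bin_on='raw'`` (default) cuts percentiles on raw scores; ``'residual'``
    cuts them on the residualised scores instead.
    """
    raw = compute_prs(genotypes, panel, endpoint, missing_policy)
    residual = residualize(raw, covariates) if covariates is not None else None
    labels = None
    if control_mask is not None:
        basis = residual if (bin_on == "residual" and residual is not None) else raw
        labels, _ = assign_percentiles(basis, control_mask, scheme)
    return PRSResult(genotypes.individual_ids, raw, residual, labels)
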