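"""Null-model GLM fitting and studentized score residuals.

The score for sample i is

    S_i = (y_i - mu_hat_i) / sqrt(Var_hat(y_i - mu_hat_i)),

where mu_hat_i comes from the *null* model that regresses the trait on
an intercept and the covariates only (no genotype terms).  Gaussian
traits use an identity link and internal studentization
(residual / (sigma_hat * sqrt(1 - h_i)) with h_i the leverage);
binomial traits use a logit link and leverage-adjusted Pearson
residuals.  A positive score marks a sample whose trait exceeds its
covariate-predicted value — the residual mass that the cell classifier
partitions into high- and low-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from fgmdr.io_formats import PhenotypeTable


class DegenerateFitError(ValueError):
    """Null fit leaves no usable residual variation (constant trait, perfect fit, separation)."""


@dataclass
class NullModelFit:
    """Covariate-only GLM fit (genotype coefficients fixed at zero)."""

    family: str
    intercept: float
    coefficients: np.ndarray  # covariate coefficients, may be empty
    fitted: np.ndarray  # mu_hat_i
    leverage: np.ndarray  # hat-matrix diagonal h_i
    dispersion: float  # sigma^2 for gaussian, 1.0 for binomial


@dataclass
class ScoreVector:
    """Per-sample studentized residual scores from the null model."""

    s: np.ndarray
    family: str

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.all(np.isfinite(self.s)):
            raise ValueError("score vector contains non-finite entries")

    @property
    def link(self) -> str:
        return "identity" if self.family == "gaussian" else "logit"


def _design(phenos: PhenotypeTable) -> np.ndarray:
    z = phenos.covariate_matrix
    x = np.column_stack([np.ones(phenos.n_samples), z]) if z.shape[1] else np.ones((phenos.n_samples, 1))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ["(intercept)"] + list(phenos.covariates.columns)
        raise ValueError(f"rank-deficient design matrix (rank {rank} < {x.shape[1]}); columns: {names}")
    return x


def fit_null_model(phenos: PhenotypeTable) -> NullModelFit:
    """Fit the covariate-only null GLM for the trait.

    Gaussian traits: ordinary least squares with identity link.
    Binomial traits: logistic regression by maximum likelihood.
    """
    x = _design(phenos)
    y = phenos.y
    if phenos.trait_family == "gaussian":
        res = sm.OLS(y, x).fit()
        hat = res.get_influence().hat_matrix_diag
        df_resid = max(res.df_resid, 1.0)
        sigma2 = float(np.sum(res.resid**2) / df_resid)
        return NullModelFit(
            family="gaussian",
            intercept=float(res.params[0]),
            coefficients=np.asarray(res.params[1:]),
            fitted=np.asarray(res.fittedvalues),
            leverage=np.asarray(hat),
            dispersion=sigma2,
        )
    model = sm.GLM(y, x, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise DegenerateFitError(f"logit null fit failed: {exc}") from exc
    if not res.converged:
        raise DegenerateFitError(
            f"logit null fit did not converge in {res.fit_history['iteration']} iterations"
        )
    hat = res.get_influence().hat_matrix_diag
    return NullModelFit(
        family="binomial",
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1:]),
        fitted=np.asarray(res.fittedvalues),
        leverage=np.asarray(hat),
        dispersion=1.0,
    )


def studentized_scores(
    fit: NullModelFit, phenos: PhenotypeTable, variant: str = "internal"
) -> ScoreVector:
    """Studentized residual scores S_i from a null-model fit.

    ``variant`` selects the studentization: ``internal`` (default,
    leverage-adjusted), ``pearson`` (no leverage adjustment) or ``none``
    (raw residuals).
    """
    if variant not in ("internal", "pearson", "none"):
        raise ValueError(f"unknown studentization variant {variant!r}")
    y = phenos.y
    mu = fit.fitted
    resid = y - mu
    if fit.family == "gaussian":
        if fit.dispersion <= 0 or not np.any(np.abs(resid) > 1e-12 * max(1.0, np.abs(y).max())):
            raise DegenerateFitError(
                "null model fits the trait exactly: residual variance is zero, every cell would tie"
            )
        if variant == "none":
            s = resid
        else:
            denom = np.sqrt(fit.dispersion)
            if variant == "internal":
                denom = denom * np.sqrt(np.clip(1.0 - fit.leverage, 1e-12, None))
            s = resid / denom
    else:
        eps = 1e-10
        if np.any(mu <= eps) or np.any(mu >= 1 - eps):
            raise DegenerateFitError("fitted probabilities of 0 or 1: quasi-separation in the null fit")
        if variant == "none":
            s = resid
        else:
            s = resid / np.sqrt(mu * (1.0 - mu))
            if variant == "internal":
                s = s / np.sqrt(np.clip(1.0 - fit.leverage, 1e-12, None))
    return ScoreVector(s=s, family=fit.family)


def scores_for(phenos: PhenotypeTable, use_covariates: bool = True, variant: str = "internal") -> ScoreVector:
    """Convenience: fit the null model and return scores in one call.

    ``use_covariates=False`` drops the covariates (intercept-only fit),
    which is how the covariate-blind MDR/FMDR variants obtain their
    scores.
    """
    if use_covariates:
        return studentized_scores(fit_null_model(phenos), phenos, variant)
    stripped = PhenotypeTable(
        samples=phenos.samples, y=phenos.y.copy(), trait_family=phenos.trait_family
    )
    return studentized_scores(fit_null_model(stripped), stripped, variant)
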