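"""Inbreeding-depression regressions.

Reproductive success (offspring counts) is regressed on the first
principal axis of five environmental covariates and on genomic inbreeding
with a Poisson log-link GLM:

    log E[F_i] = alpha + beta1 * X_i1 + gamma * I_i

Stem circumference uses an ordinary linear model with felling age as an
additional covariate.  Independent variables are centered so the intercept
is the population phenotypic mean; centering leaves slopes, their standard
errors and p-values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["env_pca", "fit_offspring_glm", "fit_growth_lm", "RegressionResult"]


@dataclass
class RegressionResult:
    coefficients: pd.Series
    stderr: pd.Series
    pvalues: pd.Series
    converged: bool
    deviance: float | None = None
    r2_adj: float | None = None

    @property
    def gamma(self) -> float:
        """The inbreeding coefficient estimate."""
        return float(self.coefficients["inbreeding"])

    def gamma_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        g, se = self.gamma, float(self.stderr["inbreeding"])
        return (g - z * se, g + z * se)


def env_pca(env: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Scores on the first principal axis of the environmental covariates.

    Variables are standardized (zero mean, unit variance) before the
    eigendecomposition; the sign is fixed so the loading of the first
    variable is non-negative.
    """
    X = np.asarray(env, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two individuals and a 2-D table")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant environmental variable")
    Z = (X - X.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    if v[0] < 0:
        v = -v
    return Z @ v


def _design(covariates: dict) -> tuple[np.ndarray, list]:
    names = list(covariates)
    cols = []
    for nm in names:
        x = np.asarray(covariates[nm], dtype=float)
        cols.append(x - x.mean())  # center: intercept = phenotypic mean
    X = np.column_stack([np.ones(len(cols[0]))] + cols)
    return X, ["intercept"] + names


def fit_offspring_glm(
    offspring: np.ndarray, x1: np.ndarray, inbreeding: np.ndarray
) -> RegressionResult:
    """Poisson log-link GLM of offspring counts on (centered) environment
    score and inbreeding, fitted by iteratively reweighted least squares."""
    y = np.asarray(offspring, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("offspring counts must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("degenerate response: all counts are zero")
    X, names = _design({"env_pc1": x1, "inbreeding": inbreeding})
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    return RegressionResult(
        coefficients=pd.Series(res.params, index=names),
        stderr=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        converged=bool(getattr(res, "converged", True)),
        deviance=float(res.deviance),
    )


def fit_growth_lm(
    circumference: np.ndarray, x1: np.ndarray, inbreeding: np.ndarray, age: np.ndarray
) -> RegressionResult:
    """Ordinary least squares of circumference on centered environment
    score, inbreeding and felling age."""
    y = np.asarray(circumference, dtype=float)
    X, names = _design({"env_pc1": x1, "inbreeding": inbreeding, "age": age})
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        coefficients=pd.Series(res.params, index=names),
        stderr=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        converged=True,
        r2_adj=float(res.rsquared_adj),
    )
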