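"""De-biased entrywise inference for linear contrasts of precision matrices.

Penalized estimates are biased toward sparsity, so their entries are not
asymptotically normal.  The one-step correction

    Theta_d[k] = 2 Theta[k] - Theta[k] Sigma[k] Theta[k]

removes the first-order bias, and sqrt(n) (Theta_d[k] - Theta0[k])_ij is
asymptotically N(0, Theta_ii Theta_jj + Theta_ij^2) entrywise.  For a linear
contrast sum_k a_k Theta0[k]_ij = 0 the test statistic is the same
combination of de-biased entries, standardized by the plug-in variance
sum_k a_k^2 (Theta[k]_ii Theta[k]_jj + Theta[k]_ij^2) / n_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .solver import CovarianceSet, PrecisionSet

__all__ = [
    "ContrastSpec",
    "TestResultMatrix",
    "debias",
    "variance_estimate",
    "linear_test",
    "confidence_intervals",
    "benjamini_hochberg",
]


@dataclass
class ContrastSpec:
    """Contrast coefficients a_1..a_K and a significance level."""

    coefficients: tuple[float, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.coefficients = tuple(float(a) for a in self.coefficients)
        if all(a == 0 for a in self.coefficients):
            raise ValueError("at least one contrast coefficient must be nonzero")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class TestResultMatrix:
    """Entrywise statistics for one linear contrast of K precision matrices."""

    statistic: np.ndarray  # T_ij = sum_k a_k Theta_d[k]_ij
    stderr: np.ndarray  # sqrt(sum_k a_k^2 var_k / n_k)
    zscores: np.ndarray
    pvalues: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    contrast: ContrastSpec
    variant: str = "plain"
    variable_names: list[str] = field(default_factory=list)

    @property
    def dimension(self) -> int:
        return self.statistic.shape[0]

    def reject(self, alpha: float | None = None) -> np.ndarray:
        """Boolean rejection matrix |z| > xi_{alpha/2}."""
        alpha = self.contrast.alpha if alpha is None else alpha
        return np.abs(self.zscores) > stats.norm.ppf(1.0 - alpha / 2.0)


def debias(theta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """One-step de-biased estimator 2*Theta - Theta @ Sigma @ Theta.

    The output is symmetrized as (M + M.T)/2 to absorb floating-point
    asymmetry; Theta = Sigma^-1 is a fixed point.
    """
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if theta.shape != cov.shape or theta.ndim != 2:
        raise ValueError(f"shape mismatch: {theta.shape} vs {cov.shape}")
    m = 2.0 * theta - theta @ cov @ theta
    return (m + m.T) / 2.0


def variance_estimate(thetas: PrecisionSet | np.ndarray, contrast: ContrastSpec) -> np.ndarray:
    """Plug-in asymptotic variance sum_k a_k^2 (Theta_ii Theta_jj + Theta_ij^2).

    This is the variance of the sqrt(n)-scaled statistic (no 1/n factor).
    """
    T = thetas.estimates if isinstance(thetas, PrecisionSet) else np.asarray(thetas, float)
    if T.ndim == 2:
        T = T[None]
    if T.shape[0] != len(contrast.coefficients):
        raise ValueError(
            f"{len(contrast.coefficients)} coefficients for {T.shape[0]} groups"
        )
    var = np.zeros(T.shape[1:])
    for a_k, theta in zip(contrast.coefficients, T):
        d = np.diag(theta)
        var += a_k**2 * (np.outer(d, d) + theta**2)
    return var


def linear_test(
    thetas: PrecisionSet,
    covs: CovarianceSet,
    contrast: ContrastSpec,
) -> TestResultMatrix:
    """Entrywise z-test of H0: sum_k a_k Theta0[k]_ij = 0 for every (i, j).

    The de-biasing product always uses the sample covariances Sigma[k] —
    also in the weighted variant, where Theta_w enters both the de-biasing
    and the variance plug-in.  Standard errors use per-group sizes:
    se_ij^2 = sum_k a_k^2 (Theta_ii Theta_jj + Theta_ij^2) / n_k, which
    reduces to the equal-n sqrt(n) scaling when all groups match.
    """
    if thetas.n_groups != len(contrast.coefficients):
        raise ValueError(
            f"{len(contrast.coefficients)} coefficients for {thetas.n_groups} groups"
        )
    T = thetas.estimates
    stat = np.zeros((thetas.dimension, thetas.dimension))
    se2 = np.zeros_like(stat)
    for k, a_k in enumerate(contrast.coefficients):
        theta_d = debias(T[k], covs.covariances[k])
        stat += a_k * theta_d
        d = np.diag(T[k])
        se2 += a_k**2 * (np.outer(d, d) + T[k] ** 2) / covs.group_sizes[k]
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, stat / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    result = TestResultMatrix(
        statistic=stat,
        stderr=se,
        zscores=z,
        pvalues=pvals,
        ci_lower=np.empty_like(stat),
        ci_upper=np.empty_like(stat),
        contrast=contrast,
        variant=thetas.variant,
    )
    confidence_intervals(result, contrast.alpha)
    return result


def confidence_intervals(result: TestResultMatrix, alpha: float) -> TestResultMatrix:
    """Set T_ij ± xi_{alpha/2} * se_ij in place (exact normal quantile)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    result.ci_lower = result.statistic - q * result.stderr
    result.ci_upper = result.statistic + q * result.stderr
    return result


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values over the upper-triangle off-diagonal entries.

    Offered as an extension for edge discovery; the core method reports raw
    entrywise p-values.  Returns a symmetric matrix with diagonal unchanged.
    """
    p = pvalues.shape[0]
    iu = np.triu_indices(p, k=1)
    raw = pvalues[iu]
    m = raw.size
    order = np.argsort(raw)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((raw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = pvalues.copy()
    out[iu] = adj
    out[(iu[1], iu[0])] = adj
    return out
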