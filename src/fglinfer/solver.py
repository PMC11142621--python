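"""Fused graphical lasso solver (plain and correlation-weighted variants).

The estimator jointly minimizes, over symmetric positive-definite matrices
Theta[1..K],

    sum_k { tr(S[k] Theta[k]) - log det Theta[k] }
        + lambda * sum_k ||offdiag(Theta[k])||_1
        + rho * sum_{k<k'} ||offdiag(Theta[k] - Theta[k'])||_1

where S[k] are per-group sample covariance (or correlation) matrices.  The
lasso term sparsifies each precision matrix; the fusion term shrinks
between-group differences toward zero, borrowing strength when networks are
similar.  Diagonals are never penalized.

The solver is a scaled consensus ADMM: the Theta-update has a closed form via
eigendecomposition, the Z-update is an exact entrywise fused-lasso proximal
operator, and U accumulates the scaled duals.  Exact zeros (the reported
support) live in the consensus variable Z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .simulate import GroupDataset

__all__ = [
    "CovarianceSet",
    "PenaltySpec",
    "AdmmOptions",
    "PrecisionSet",
    "sample_covariance",
    "correlation_from_cov",
    "fused_prox",
    "fgl_admm",
    "weighted_fgl",
    "objective",
    "kkt_residual",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class CovarianceSet:
    """Per-group sample covariance (or correlation) matrices."""

    covariances: np.ndarray  # (K, p, p)
    group_sizes: list[int]
    is_correlation: bool = False
    scale_roots: np.ndarray | None = None  # (K, p) diag of W = diag(Sigma)^(1/2)

    def __post_init__(self) -> None:
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        for k, s in enumerate(self.covariances):
            if not np.allclose(s, s.T, atol=_SYM_TOL):
                raise ValueError(f"covariance {k} is not symmetric")
            if self.is_correlation and not np.allclose(
                np.diag(s), 1.0, atol=_SYM_TOL
            ):
                raise ValueError(f"correlation matrix {k} lacks a unit diagonal")

    @property
    def n_groups(self) -> int:
        return self.covariances.shape[0]

    @property
    def dimension(self) -> int:
        return self.covariances.shape[1]


@dataclass
class PenaltySpec:
    """Regularization strengths: ``lasso`` is lambda, ``fusion`` is rho."""

    lasso: float
    fusion: float
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.lasso < 0 or self.fusion < 0:
            raise ValueError("penalty parameters must be nonnegative")


@dataclass
class AdmmOptions:
    """ADMM controls.  Tolerances default to 1e-5 * p at solve time."""

    step: float = 1.0
    max_iter: int = 1000
    tol_primal: float | None = None
    tol_dual: float | None = None

    def __post_init__(self) -> None:
        if self.step <= 0 or self.max_iter <= 0:
            raise ValueError("step and max_iter must be positive")
        for tol in (self.tol_primal, self.tol_dual):
            if tol is not None and tol <= 0:
                raise ValueError("tolerances must be positive")

    def resolved_tols(self, p: int) -> tuple[float, float]:
        default = 1e-5 * p
        return (
            self.tol_primal if self.tol_primal is not None else default,
            self.tol_dual if self.tol_dual is not None else default,
        )


@dataclass
class PrecisionSet:
    """Fitted precision matrices with convergence metadata.

    ``estimates`` are the (dense, strictly PD) Theta iterates; ``consensus``
    is the exactly-sparse Z iterate whose zero pattern defines the reported
    support.  For the weighted variant, ``estimates`` holds Theta_w (on the
    original covariance scale) and ``correlation_estimates`` holds Theta_R,
    the inverse-correlation fit they were derived from.
    """

    estimates: np.ndarray  # (K, p, p)
    consensus: np.ndarray  # (K, p, p)
    penalty: PenaltySpec
    variant: str = "plain"  # "plain" | "weighted"
    converged: bool = True
    iterations: int = 0
    primal_residual: float = 0.0
    dual_residual: float = 0.0
    correlation_estimates: np.ndarray | None = None
    scale_roots: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return self.estimates.shape[0]

    @property
    def dimension(self) -> int:
        return self.estimates.shape[1]

    def edge_counts(self) -> list[int]:
        """Nonzero upper-triangle off-diagonal entries per group (from Z)."""
        p = self.dimension
        iu = np.triu_indices(p, k=1)
        return [int(np.count_nonzero(z[iu])) for z in self.consensus]


def sample_covariance(data: GroupDataset, center: bool = False) -> CovarianceSet:
    """Per-group sample covariances Sigma[k] = (1/n_k) sum_i x_i x_i^T.

    With ``center=True`` the column means are subtracted first (the divisor
    stays n_k).  Simulated data are zero-mean by construction, so centering
    defaults to off; real data should center.
    """
    covs = []
    for x in data.observations:
        x = np.asarray(x, dtype=float)
        if center:
            x = x - x.mean(axis=0)
        covs.append(x.T @ x / x.shape[0])
    return CovarianceSet(np.stack(covs), data.group_sizes)


def correlation_from_cov(covs: CovarianceSet) -> CovarianceSet:
    """Convert covariances to correlations R = W^-1 Sigma W^-1, W = diag(Sigma)^1/2."""
    roots = np.sqrt(np.stack([np.diag(s) for s in covs.covariances]))
    if np.any(roots <= 0) or not np.all(np.isfinite(roots)):
        raise ValueError("every variance must be strictly positive")
    corr = covs.covariances / roots[:, :, None] / roots[:, None, :]
    for r in corr:  # enforce exact unit diagonal against round-off
        np.fill_diagonal(r, 1.0)
    return CovarianceSet(corr, covs.group_sizes, is_correlation=True, scale_roots=roots)


# ---------------------------------------------------------------------------
# fused-lasso proximal operator
# ---------------------------------------------------------------------------

def _pairwise_fusion_cost(z: np.ndarray) -> np.ndarray:
    """sum_{k<k'} |z_k - z_k'| along axis 0 of a (K, m) array."""
    K = z.shape[0]
    cost = np.zeros(z.shape[1:])
    for a in range(K):
        for b in range(a + 1, K):
            cost += np.abs(z[a] - z[b])
    return cost


def _fusion_prox(a: np.ndarray, rho: float) -> np.ndarray:
    """argmin_z 0.5*sum_k (z_k - a_k)^2 + rho*sum_{k<k'} |z_k - z_k'|.

    ``a`` has shape (K, m); the prox is applied columnwise.  The minimizer
    preserves the ordering of ``a``, so the optimum realizes one of the
    2^(K-1) contiguous partitions of the sorted values into fused blocks;
    all candidates are enumerated and the best feasible one selected.
    """
    K, m = a.shape
    if K == 1 or rho == 0.0:
        return a.copy()
    if K == 2:
        half_gap = (a[0] - a[1]) / 2.0
        fused = np.abs(half_gap) <= rho
        mean = (a[0] + a[1]) / 2.0  # fused entries share one exact value
        shift = rho * np.sign(half_gap)
        return np.stack([
            np.where(fused, mean, a[0] - shift),
            np.where(fused, mean, a[1] + shift),
        ])

    order = np.argsort(a, axis=0, kind="stable")
    cols = np.arange(m)
    b = a[order, cols]  # sorted ascending
    best = None
    best_cost = np.full(m, np.inf)
    for mask in product([0, 1], repeat=K - 1):  # 1 = block boundary after slot
        bounds = [0] + [i + 1 for i, cut in enumerate(mask) if cut] + [K]
        z = np.empty_like(b)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n_lower, n_higher = lo, K - hi
            v = b[lo:hi].mean(axis=0) - rho * (n_lower - n_higher)
            z[lo:hi] = v
        feasible = np.ones(m, dtype=bool)
        for cut in range(1, len(bounds) - 1):
            feasible &= z[bounds[cut]] >= z[bounds[cut] - 1]
        cost = 0.5 * ((z - b) ** 2).sum(axis=0) + rho * _pairwise_fusion_cost(z)
        cost = np.where(feasible, cost, np.inf)
        improve = cost < best_cost
        if best is None:
            best, best_cost = z, cost
        else:
            best[:, improve] = z[:, improve]
            best_cost = np.minimum(best_cost, cost)
    out = np.empty_like(a)
    out[order, cols] = best
    return out


def _fgl_entry_prox(a: np.ndarray, lasso: float, fusion: float) -> np.ndarray:
    """Prox of lasso + pairwise fusion: fuse first, then soft-threshold.

    The composition is exact because soft-thresholding is monotone, so it
    can only enlarge the fusion penalty's subdifferential.
    """
    z = _fusion_prox(a, fusion)
    return np.sign(z) * np.maximum(np.abs(z) - lasso, 0.0)


def fused_prox(
    values,
    step: float,
    lasso: float,
    fusion: float,
    is_diagonal: bool = False,
) -> np.ndarray:
    """Exact minimizer of the ADMM Z-subproblem for one matrix entry.

    Minimizes ``sum_k (step/2)(z_k - a_k)^2`` plus, for off-diagonal entries,
    ``lasso * sum_k |z_k| + fusion * sum_{k<k'} |z_k - z_k'|``.  Diagonal
    entries pass through unchanged.
    """
    a = np.asarray(values, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    if lasso < 0 or fusion < 0:
        raise ValueError("penalties must be nonnegative")
    if is_diagonal:
        return a.copy()
    return _fgl_entry_prox(a[:, None], lasso / step, fusion / step)[:, 0]


# ---------------------------------------------------------------------------
# ADMM
# ---------------------------------------------------------------------------

def _theta_update(target: np.ndarray, mu: float) -> np.ndarray:
    """argmin tr(S Theta) - logdet Theta + (mu/2)||Theta - C||_F^2 given
    target = mu*C - S; the closed form via eigendecomposition is always PD."""
    d, v = np.linalg.eigh(target)
    theta_eig = (d + np.sqrt(d * d + 4.0 * mu)) / (2.0 * mu)
    return (v * theta_eig) @ v.T


def fgl_admm(
    covs: CovarianceSet,
    penalty: PenaltySpec,
    opts: AdmmOptions | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> PrecisionSet:
    """Solve the fused graphical lasso by consensus ADMM.

    Parameters
    ----------
    covs
        Sample covariance (or correlation) matrices for the K groups.
    penalty
        lambda (lasso) and rho (fusion); rho is ignored when K = 1.
    opts
        Step size, iteration cap and residual tolerances.
    init
        Optional warm start ``(Z, U)`` from a previous solve.

    Returns
    -------
    PrecisionSet
        With ``converged=False`` (and a logged warning) if the residual
        criteria were not met within ``max_iter`` — never a silent failure.
    """
    opts = opts or AdmmOptions()
    S = covs.covariances
    K, p, _ = S.shape
    mu = opts.step
    tol_primal, tol_dual = opts.resolved_tols(p)
    fusion = penalty.fusion if K > 1 else 0.0

    if init is not None:
        Z, U = init[0].copy(), init[1].copy()
    else:
        Z = np.stack([np.diag(1.0 / np.clip(np.diag(s), 1e-12, None)) for s in S])
        U = np.zeros_like(S)
    Theta = Z.copy()

    iu = np.triu_indices(p, k=1)
    r_primal = r_dual = np.inf
    it = 0
    for it in range(1, opts.max_iter + 1):
        for k in range(K):
            Theta[k] = _theta_update(mu * (Z[k] - U[k]) - S[k], mu)
        A = Theta + U
        Z_old = Z
        Z = A.copy()
        # entrywise prox on the upper triangle, mirrored (inputs are symmetric)
        z_off = _fgl_entry_prox(A[:, iu[0], iu[1]], penalty.lasso / mu, fusion / mu)
        Z[:, iu[0], iu[1]] = z_off
        Z[:, iu[1], iu[0]] = z_off
        U = U + Theta - Z
        r_primal = float(np.sqrt(((Theta - Z) ** 2).sum()))
        r_dual = float(mu * np.sqrt(((Z - Z_old) ** 2).sum()))
        if r_primal <= tol_primal and r_dual <= tol_dual:
            break

    converged = r_primal <= tol_primal and r_dual <= tol_dual
    if not converged:
        logger.warning(
            "fused graphical lasso ADMM did not converge in %d iterations "
            "(primal %.3e > %.3e or dual %.3e > %.3e)",
            opts.max_iter, r_primal, tol_primal, r_dual, tol_dual,
        )
    Theta = (Theta + np.transpose(Theta, (0, 2, 1))) / 2.0
    return PrecisionSet(
        estimates=Theta,
        consensus=Z,
        penalty=penalty,
        variant="plain",
        converged=converged,
        iterations=it,
        primal_residual=r_primal,
        dual_residual=r_dual,
    )


def weighted_fgl(
    covs: CovarianceSet,
    penalty: PenaltySpec,
    opts: AdmmOptions | None = None,
) -> PrecisionSet:
    """Correlation-weighted fused graphical lasso.

    Solves the plain problem on the sample correlation matrices R[k] to get
    Theta_R[k], then back-transforms Theta_w[k] = W[k]^-1 Theta_R[k] W[k]^-1
    where W[k] = diag(Sigma[k])^(1/2).  This penalizes entries on the
    correlation scale, so variables with large variances are not
    under-penalized.
    """
    corr = correlation_from_cov(covs) if not covs.is_correlation else covs
    fit = fgl_admm(corr, penalty, opts)
    roots = corr.scale_roots
    if roots is None:  # input was already a correlation set
        roots = np.ones((covs.n_groups, covs.dimension))
    inv = 1.0 / roots
    theta_w = fit.estimates * inv[:, :, None] * inv[:, None, :]
    consensus_w = fit.consensus * inv[:, :, None] * inv[:, None, :]
    return PrecisionSet(
        estimates=theta_w,
        consensus=consensus_w,
        penalty=PenaltySpec(penalty.lasso, penalty.fusion, weighted=True),
        variant="weighted",
        converged=fit.converged,
        iterations=fit.iterations,
        primal_residual=fit.primal_residual,
        dual_residual=fit.dual_residual,
        correlation_estimates=fit.estimates,
        scale_roots=roots,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _as_theta_array(thetas) -> np.ndarray:
    if isinstance(thetas, PrecisionSet):
        return thetas.estimates
    arr = np.asarray(thetas, dtype=float)
    return arr[None] if arr.ndim == 2 else arr


def objective(covs: CovarianceSet, thetas, penalty: PenaltySpec) -> float:
    """Penalized negative log-likelihood of Theta[1..K] (unscaled by n_k)."""
    T = _as_theta_array(thetas)
    S = covs.covariances
    total = 0.0
    for k in range(T.shape[0]):
        sign, logdet = np.linalg.slogdet(T[k])
        if sign <= 0:
            raise ValueError(f"estimate {k} is not positive definite")
        off = T[k] - np.diag(np.diag(T[k]))
        total += float(np.trace(S[k] @ T[k]) - logdet)
        total += penalty.lasso * float(np.abs(off).sum())
    for a in range(T.shape[0]):
        for b in range(a + 1, T.shape[0]):
            diff = T[a] - T[b]
            diff = diff - np.diag(np.diag(diff))
            total += penalty.fusion * float(np.abs(diff).sum())
    return total


def kkt_residual(
    covs: CovarianceSet,
    thetas: PrecisionSet,
    penalty: PenaltySpec,
    tie_tol: float = 1e-9,
) -> np.ndarray:
    """Per-group maximum violation of the stationarity conditions.

    For each group the gradient of the smooth part, G[k] = Sigma[k] -
    Theta[k]^-1, must be cancelled by a subgradient of the off-diagonal
    penalty.  Sign patterns (and ties) are read from the exactly sparse
    consensus variable.  Entries whose subgradient is not pinned down
    (zeros, fused pairs) contribute only the amount by which |G + fixed
    part| exceeds the available slack.
    """
    T = thetas.estimates
    Z = thetas.consensus
    K, p, _ = T.shape
    offmask = ~np.eye(p, dtype=bool)
    viol = np.zeros(K)
    for k in range(K):
        base = covs.covariances[k] - np.linalg.inv(T[k])
        zero = np.abs(Z[k]) <= tie_tol
        fixed = penalty.lasso * np.sign(Z[k]) * ~zero
        slack = penalty.lasso * zero.astype(float)
        for kk in range(K):
            if kk == k:
                continue
            diff = Z[k] - Z[kk]
            tied = np.abs(diff) <= tie_tol
            fixed = fixed + penalty.fusion * np.sign(diff) * ~tied
            slack = slack + penalty.fusion * tied.astype(float)
        off_viol = np.maximum(np.abs(base + fixed) - slack, 0.0)[offmask]
        diag_viol = np.abs(np.diag(base))
        viol[k] = max(off_viol.max(initial=0.0), diag_viol.max(initial=0.0))
    return viol
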