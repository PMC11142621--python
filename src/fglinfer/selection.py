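"""AIC tuning-parameter selection over a (lambda, rho) grid.

AIC = sum_k [ n_k tr(S[k] Theta[k]) - n_k logdet Theta[k] + 2 E_k ],
where E_k counts the nonzero upper-triangle off-diagonal entries of the
exactly sparse consensus estimate — the per-group degrees of freedom of the
fitted graph.  The default grid is 30 equally spaced points from 0.05 to 0.3
on each axis (step 0.25/29 ≈ 0.0086).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solver import AdmmOptions, CovarianceSet, PenaltySpec, PrecisionSet, fgl_admm, weighted_fgl

__all__ = ["TuningGrid", "aic", "select_tuning"]


def _default_axis() -> list[float]:
    return list(np.linspace(0.05, 0.3, 30))


@dataclass
class TuningGrid:
    lasso_values: list[float] = field(default_factory=_default_axis)
    fusion_values: list[float] = field(default_factory=_default_axis)

    def __post_init__(self) -> None:
        if len(self.lasso_values) == 0 or len(self.fusion_values) == 0:
            raise ValueError("the tuning grid must be nonempty")
        if any(v < 0 for v in list(self.lasso_values) + list(self.fusion_values)):
            raise ValueError("tuning values must be nonnegative")
        # ascending order makes the smallest-(lambda, rho) tie-break automatic
        self.lasso_values = sorted(float(v) for v in self.lasso_values)
        self.fusion_values = sorted(float(v) for v in self.fusion_values)


def aic(covs: CovarianceSet, thetas: PrecisionSet) -> float:
    """Akaike information criterion for a joint graphical-lasso fit."""
    total = 0.0
    edges = thetas.edge_counts()
    for k in range(thetas.n_groups):
        n_k = covs.group_sizes[k]
        theta = thetas.estimates[k]
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            raise ValueError(f"estimate {k} is not positive definite")
        fit = float(np.trace(covs.covariances[k] @ theta)) - logdet
        total += n_k * fit + 2.0 * edges[k]
    return total


def select_tuning(
    covs: CovarianceSet,
    grid: TuningGrid | None = None,
    opts: AdmmOptions | None = None,
    weighted: bool = False,
) -> tuple[float, float, PrecisionSet, pd.DataFrame]:
    """Fit every (lambda, rho) pair and return the AIC minimizer.

    Ties break toward the smallest lambda, then the smallest rho.  The
    search warm-starts along the rho axis; solutions are insensitive to the
    start at the solver tolerance.  Non-converged fits are recorded in the
    surface with ``converged=False`` and excluded from the argmin.

    Returns ``(lambda*, rho*, best_fit, surface)`` where ``surface`` is a
    DataFrame with columns lasso, fusion, aic, converged.
    """
    grid = grid or TuningGrid()
    opts = opts or AdmmOptions()
    rows = []
    best = None  # (aic, lasso, fusion, fit)
    for lam in grid.lasso_values:
        warm = None
        for rho in grid.fusion_values:
            penalty = PenaltySpec(lam, rho, weighted=weighted)
            if weighted:
                fit = weighted_fgl(covs, penalty, opts)
                warm = None
            else:
                fit = fgl_admm(covs, penalty, opts, init=warm)
                warm = (fit.consensus, np.zeros_like(fit.consensus))
            score = aic(covs, fit) if fit.converged else np.nan
            rows.append(
                {"lasso": lam, "fusion": rho, "aic": score, "converged": fit.converged}
            )
            if fit.converged and (best is None or score < best[0] - 1e-12):
                best = (score, lam, rho, fit)
    surface = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no (lambda, rho) pair converged on the grid")
    return best[1], best[2], best[3], surface
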