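"""Monte-Carlo experiments: CI coverage and fluctuation of the test statistic.

Two experiment families mirror the method's evaluation protocol:

* **Coverage** — repeatedly generate a null ground truth, sample Gaussian
  groups, fit the fused graphical lasso, form 95% de-biased confidence
  intervals for the linear contrast (whose true value is zero under the
  null), and record per-entry coverage frequencies averaged over the true
  support S and its complement S^c.
* **Fluctuation** — record the standardized statistic z_ij at selected
  entries across replications and summarize its closeness to N(0, 1)
  (mean, variance, Kolmogorov–Smirnov distance).

Defaults mirror the study conditions: p=100, n in {200, 400}, 500
replications, nominal level 0.05.  Tuning is either a fixed (lambda, rho)
pair — the scaled-down configuration uses the theoretical rate
lambda = rho = sqrt(log p / n) — or a full AIC grid search per replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .inference import (
    ContrastSpec,
    TestResultMatrix,
    confidence_intervals,
    debias,
    linear_test,
)
from .selection import TuningGrid, select_tuning
from .simulate import SparseGroundTruth, make_null_scenario, sample_groups
from .solver import AdmmOptions, PenaltySpec, fgl_admm, sample_covariance, weighted_fgl

__all__ = [
    "SimConfig",
    "CoverageReport",
    "FluctuationReport",
    "rate_penalty",
    "default_contrast",
    "run_coverage_experiment",
    "run_fluctuation_experiment",
]


def rate_penalty(p: int, n: int) -> float:
    """Theoretical tuning rate sqrt(log p / n)."""
    return float(np.sqrt(np.log(p) / n))


@dataclass
class SimConfig:
    """One experiment cell.

    ``tuning`` is ``"fixed"`` (use ``lasso``/``fusion``; either may be None
    to mean the sqrt(log p / n) rate) or ``"grid"`` (AIC search over
    ``grid`` per replication).  ``redraw_truth`` draws a fresh ground truth
    every replication; with ``False`` one truth is shared by all
    replications.  ``include_diagonal_in_support`` keeps diagonal entries
    (always nonzero) inside S when averaging coverage.
    """

    scenario: str = "equal"
    p: int = 100
    n: int | Sequence[int] = 200
    alpha_tildes: float | tuple[float, ...] = 0.1
    coeffs: tuple[float, ...] = ()
    contrast: tuple[float, ...] | None = None
    replications: int = 500
    alpha: float = 0.05
    tuning: str = "fixed"
    lasso: float | None = None
    fusion: float | None = None
    grid: TuningGrid | None = None
    weighted: bool = False
    redraw_truth: bool = True
    include_diagonal_in_support: bool = True
    oracle: bool = False
    max_redraw_fraction: float = 0.1
    admm: AdmmOptions = field(default_factory=AdmmOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not self.coeffs:
            self.coeffs = {
                "equal": (),
                "linear": (0.5,),
                "three_sample_linear": (0.6, 0.9),
            }[self.scenario]
        if self.contrast is None:
            self.contrast = default_contrast(self.scenario, self.coeffs)

    def group_sizes(self) -> list[int]:
        k = {"equal": 2, "linear": 2, "three_sample_linear": 3}[self.scenario]
        if np.isscalar(self.n):
            return [int(self.n)] * k
        return [int(v) for v in self.n]


def default_contrast(scenario: str, coeffs: tuple[float, ...]) -> tuple[float, ...]:
    """Contrast vector that is exactly null for the given scenario.

    equal: (1, -1); linear with Theta[2] = c*Theta[1]: (1, -1/c);
    three-sample with Theta[3] = c1*Theta[1] + c2*Theta[2]: (c1, c2, -1).
    """
    if scenario == "equal":
        return (1.0, -1.0)
    if scenario == "linear":
        c = coeffs[0] if coeffs else 0.5
        return (1.0, -1.0 / c)
    if scenario == "three_sample_linear":
        c1, c2 = coeffs if coeffs else (0.6, 0.9)
        return (c1, c2, -1.0)
    raise ValueError(f"unknown scenario {scenario!r}")


def reference_support(truth: SparseGroundTruth, include_diagonal: bool) -> np.ndarray:
    """S: nonzero entries of the scenario's reference matrix.

    For the two-sample nulls this is the support of Theta0[1]; for the
    three-sample null, of the combination c1*Theta0[1] + c2*Theta0[2].
    Both share the sparsity pattern of every group by construction.
    """
    if truth.scenario == "three_sample_linear":
        mask = truth.supports[2].copy()
    else:
        mask = truth.supports[0].copy()
    if include_diagonal:
        mask = mask | np.eye(truth.dimension, dtype=bool)
    return mask


def _resolve_penalty(config: SimConfig, p: int, n: int) -> PenaltySpec:
    lam = config.lasso if config.lasso is not None else rate_penalty(p, n)
    rho = config.fusion if config.fusion is not None else rate_penalty(p, n)
    return PenaltySpec(lam, rho, weighted=config.weighted)


@dataclass
class CoverageReport:
    """Per-entry coverage frequencies and their averages over S and S^c."""

    per_entry_coverage: np.ndarray
    avg_S: float
    avg_Sc: float
    support_used: np.ndarray  # membership counts per entry across replications
    replications: int
    redraws: int
    config: SimConfig


@dataclass
class FluctuationReport:
    """Standardized-statistic samples at selected entries."""

    entries: list[tuple[int, int]]
    samples: np.ndarray  # (replications, n_entries)
    means: np.ndarray
    variances: np.ndarray
    ks_distance: np.ndarray
    ks_pvalue: np.ndarray
    config: SimConfig


def _replicate(config: SimConfig, truth_or_seed, seed_data):
    """One replication: truth, data, fit, test.  Returns (truth, result, ok)."""
    if isinstance(truth_or_seed, SparseGroundTruth):
        truth = truth_or_seed
    else:
        truth = make_null_scenario(
            config.scenario, config.p, config.alpha_tildes, config.coeffs, truth_or_seed
        )
    data = sample_groups(truth, config.group_sizes(), seed_data)
    covs = sample_covariance(data, center=False)
    contrast = ContrastSpec(config.contrast, alpha=config.alpha)

    if config.oracle:
        # truth-based pivot: de-bias the true Theta0 and use the true variance
        stat = np.zeros((config.p, config.p))
        se2 = np.zeros_like(stat)
        for k, a_k in enumerate(contrast.coefficients):
            stat += a_k * debias(truth.precisions[k], covs.covariances[k])
            d = np.diag(truth.precisions[k])
            se2 += a_k**2 * (np.outer(d, d) + truth.precisions[k] ** 2) / covs.group_sizes[k]
        se = np.sqrt(se2)
        result = TestResultMatrix(
            statistic=stat, stderr=se, zscores=stat / se,
            pvalues=2.0 * stats.norm.sf(np.abs(stat / se)),
            ci_lower=np.empty_like(stat), ci_upper=np.empty_like(stat),
            contrast=contrast, variant="oracle",
        )
        confidence_intervals(result, config.alpha)
        return truth, result, True

    if config.tuning == "grid":
        _, _, fit, _ = select_tuning(covs, config.grid, config.admm, config.weighted)
    else:
        penalty = _resolve_penalty(config, config.p, min(covs.group_sizes))
        if config.weighted:
            fit = weighted_fgl(covs, penalty, config.admm)
        else:
            fit = fgl_admm(covs, penalty, config.admm)
        if not fit.converged:
            return truth, None, False
    return truth, linear_test(fit, covs, contrast), True


def _seed_streams(config: SimConfig, budget: int):
    ss = np.random.SeedSequence(config.seed)
    truth_children = ss.spawn(budget)
    data_children = [c.spawn(1)[0] for c in ss.spawn(budget)]
    return truth_children, data_children


def run_coverage_experiment(config: SimConfig) -> CoverageReport:
    """Empirical coverage of the de-biased CIs under the configured null.

    The true contrast value is exactly zero at every entry under the null
    scenarios, so coverage at entry (i, j) is the frequency of
    0 in [T_ij - q*se_ij, T_ij + q*se_ij].  Averages over S and S^c weight
    each replication's support equally (supports vary when the truth is
    redrawn, but their size is fixed by the exact-edge-count generator).
    """
    budget = config.replications + int(np.ceil(config.max_redraw_fraction * config.replications)) + 1
    truth_children, data_children = _seed_streams(config, budget)

    p = config.p
    cover_sum = np.zeros((p, p))
    support_count = np.zeros((p, p))
    s_cover = s_total = sc_cover = sc_total = 0.0
    done = redraws = 0
    attempt = 0
    fixed_truth = None
    if not config.redraw_truth:
        fixed_truth = make_null_scenario(
            config.scenario, config.p, config.alpha_tildes, config.coeffs,
            truth_children[0],
        )
    while done < config.replications:
        if attempt >= budget:
            raise RuntimeError(
                f"too many non-converged replications ({redraws} redraws)"
            )
        t_seed = truth_children[attempt] if config.redraw_truth else fixed_truth
        truth, result, ok = _replicate(config, t_seed, data_children[attempt])
        attempt += 1
        if not ok:
            redraws += 1
            continue
        covered = (result.ci_lower <= 0.0) & (0.0 <= result.ci_upper)
        mask = reference_support(truth, config.include_diagonal_in_support)
        cover_sum += covered
        support_count += mask
        s_cover += covered[mask].sum()
        s_total += mask.sum()
        sc_cover += covered[~mask].sum()
        sc_total += (~mask).sum()
        done += 1
    return CoverageReport(
        per_entry_coverage=cover_sum / config.replications,
        avg_S=s_cover / s_total,
        avg_Sc=sc_cover / sc_total,
        support_used=support_count,
        replications=config.replications,
        redraws=redraws,
        config=config,
    )


def run_fluctuation_experiment(
    config: SimConfig, entries: Sequence[tuple[int, int]]
) -> FluctuationReport:
    """Sample the standardized statistic at selected entries under the null.

    Returns the replication samples plus mean, variance and the KS distance
    (and p-value) against the standard normal for each entry.
    """
    entries = [tuple(e) for e in entries]
    for i, j in entries:
        if not (0 <= i < config.p and 0 <= j < config.p):
            raise ValueError(f"entry {(i, j)} outside a {config.p}x{config.p} matrix")
    budget = config.replications + int(np.ceil(config.max_redraw_fraction * config.replications)) + 1
    truth_children, data_children = _seed_streams(config, budget)
    samples = np.empty((config.replications, len(entries)))
    done = redraws = attempt = 0
    fixed_truth = None
    if not config.redraw_truth:
        fixed_truth = make_null_scenario(
            config.scenario, config.p, config.alpha_tildes, config.coeffs,
            truth_children[0],
        )
    while done < config.replications:
        if attempt >= budget:
            raise RuntimeError(
                f"too many non-converged replications ({redraws} redraws)"
            )
        t_seed = truth_children[attempt] if config.redraw_truth else fixed_truth
        _, result, ok = _replicate(config, t_seed, data_children[attempt])
        attempt += 1
        if not ok:
            redraws += 1
            continue
        samples[done] = [result.zscores[i, j] for i, j in entries]
        done += 1
    ks_d = np.empty(len(entries))
    ks_p = np.empty(len(entries))
    for idx in range(len(entries)):
        res = stats.kstest(samples[:, idx], "norm")
        ks_d[idx], ks_p[idx] = res.statistic, res.pvalue
    return FluctuationReport(
        entries=entries,
        samples=samples,
        means=samples.mean(axis=0),
        variances=samples.var(axis=0, ddof=1),
        ks_distance=ks_d,
        ks_pvalue=ks_p,
        config=config,
    )
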