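"""Synthetic sparse precision matrices and multivariate-normal group samples.

The generator builds a random symmetric graph with a prescribed fraction of
edges, fills the edges with signed weights bounded away from zero, and shifts
the diagonal so the minimum eigenvalue is exactly 0.1.  Group observations are
then drawn from zero-mean Gaussians whose covariance is the inverse of each
precision matrix — the standard testbed for differential-network inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SparseGroundTruth",
    "GroupDataset",
    "generate_graph",
    "generate_precision",
    "make_null_scenario",
    "sample_groups",
]

#: Diagonal shift added on top of |lambda_min|; pins the smallest eigenvalue.
EIGEN_FLOOR = 0.1


@dataclass
class SparseGroundTruth:
    """True precision matrices with their sparsity bookkeeping.

    Attributes
    ----------
    precisions : list of (p, p) ndarray
        Symmetric positive-definite precision matrices, one per group.
    supports : list of (p, p) ndarray of bool
        Off-diagonal support masks (True where the entry is nonzero);
        symmetric, diagonal False.
    sparsity_params : tuple of float
        Edge fraction used for each independently generated matrix.
    scenario : str
        One of ``"single"``, ``"equal"``, ``"linear"``,
        ``"three_sample_linear"``.
    coeffs : tuple of float
        Combination coefficients used by the linear scenarios.
    seed : int
        Seed the construction was derived from.
    """

    precisions: list[np.ndarray]
    supports: list[np.ndarray]
    sparsity_params: tuple[float, ...]
    scenario: str = "single"
    coeffs: tuple[float, ...] = ()
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.precisions)

    @property
    def dimension(self) -> int:
        return self.precisions[0].shape[0]

    def support_sizes(self) -> list[int]:
        """s_k: number of nonzero off-diagonal entries (both orders counted)."""
        return [int(mask.sum()) for mask in self.supports]

    def max_row_degrees(self) -> list[int]:
        """d_k: maximum number of off-diagonal nonzeros in any column."""
        return [int(mask.sum(axis=0).max()) for mask in self.supports]


@dataclass
class GroupDataset:
    """Per-group observation matrices sharing a common variable set."""

    observations: list[np.ndarray]  # each (n_k, p)
    variable_names: list[str] = field(default_factory=list)
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = {x.shape[1] for x in self.observations}
        if len(dims) > 1:
            raise ValueError(f"groups disagree on dimension: {sorted(dims)}")
        for idx, x in enumerate(self.observations):
            if x.shape[0] < 2:
                raise ValueError(
                    f"group {idx} has {x.shape[0]} sample(s); need at least 2"
                )
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(self.dimension)]
        if not self.group_names:
            self.group_names = [f"G{k + 1}" for k in range(self.n_groups)]

    @property
    def n_groups(self) -> int:
        return len(self.observations)

    @property
    def dimension(self) -> int:
        return self.observations[0].shape[1]

    @property
    def group_sizes(self) -> list[int]:
        return [x.shape[0] for x in self.observations]


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _check_graph_args(p: int, alpha_tilde: float) -> None:
    if p < 2:
        raise ValueError(f"dimension p must be >= 2, got {p}")
    if not 0.0 <= alpha_tilde <= 1.0:
        raise ValueError(f"edge fraction must lie in [0, 1], got {alpha_tilde}")


def generate_graph(
    p: int, alpha_tilde: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Random symmetric 0/1 adjacency matrix with zero diagonal.

    Exactly ``round(alpha_tilde * p*(p-1)/2)`` upper-triangle positions are
    set to 1, chosen uniformly without replacement, then mirrored.
    """
    _check_graph_args(p, alpha_tilde)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_pairs = p * (p - 1) // 2
    n_edges = int(round(alpha_tilde * n_pairs))
    iu, ju = np.triu_indices(p, k=1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    g = np.zeros((p, p), dtype=np.int64)
    g[iu[chosen], ju[chosen]] = 1
    return g + g.T


def generate_precision(
    p: int, alpha_tilde: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One sparse SPD precision matrix plus its off-diagonal support mask.

    Edge weights are ``m = (u_ij + u_ji)/2`` with U ~ i.i.d. Uniform(0, 1),
    with 1 subtracted whenever ``m < 0.5`` so every nonzero off-diagonal has
    absolute value in [0.5, 1).  The diagonal is shifted by
    ``|lambda_min| + 0.1`` which makes the smallest eigenvalue exactly 0.1.
    """
    _check_graph_args(p, alpha_tilde)
    if isinstance(seed, np.random.Generator):
        rng_graph = rng_u = seed
    else:
        ss_graph, ss_u = _as_seedseq(seed).spawn(2)
        rng_graph = np.random.default_rng(ss_graph)
        rng_u = np.random.default_rng(ss_u)
    g = generate_graph(p, alpha_tilde, rng_graph)
    u = rng_u.uniform(size=(p, p))
    m = (u + u.T) / 2.0
    theta_tilde = np.where(m < 0.5, m - 1.0, m)
    theta_tilde[g == 0] = 0.0  # indicator applies to edges only
    np.fill_diagonal(theta_tilde, 0.0)
    lam_min = np.linalg.eigvalsh(theta_tilde)[0]
    theta0 = theta_tilde + (abs(lam_min) + EIGEN_FLOOR) * np.eye(p)
    support = g.astype(bool)
    return theta0, support


def make_null_scenario(
    scenario: str,
    p: int,
    alpha_tildes: float | tuple[float, ...],
    coeffs: tuple[float, ...] = (),
    seed: int = 0,
) -> SparseGroundTruth:
    """Build the ground truth for one of the simulated null hypotheses.

    ``equal``
        Two identical matrices (two-sample equality null).
    ``linear``
        Theta0[2] = c * Theta0[1] with one positive coefficient c, so the
        contrast (1, -1/c) — or any rescaling of it — is exactly null.
    ``three_sample_linear``
        Theta0[1], Theta0[2] generated independently (with their own edge
        fractions) and Theta0[3] = c1*Theta0[1] + c2*Theta0[2].
    """
    if np.isscalar(alpha_tildes):
        alpha_tildes = (float(alpha_tildes),)
    alpha_tildes = tuple(float(a) for a in alpha_tildes)
    coeffs = tuple(float(c) for c in coeffs)
    if any(c <= 0 for c in coeffs):
        raise ValueError(
            "combination coefficients must be positive to keep every "
            f"precision matrix positive definite, got {coeffs}"
        )
    ss = _as_seedseq(seed)

    if scenario == "equal":
        if len(coeffs) != 0:
            raise ValueError("the equal scenario takes no coefficients")
        theta, supp = generate_precision(p, alpha_tildes[0], seed)
        return SparseGroundTruth(
            [theta, theta.copy()], [supp, supp.copy()],
            (alpha_tildes[0],) * 2, "equal", (), seed,
        )
    if scenario == "linear":
        if len(coeffs) != 1:
            raise ValueError("the linear scenario takes exactly one coefficient")
        theta, supp = generate_precision(p, alpha_tildes[0], seed)
        return SparseGroundTruth(
            [theta, coeffs[0] * theta], [supp, supp.copy()],
            (alpha_tildes[0],) * 2, "linear", coeffs, seed,
        )
    if scenario == "three_sample_linear":
        if len(coeffs) != 2:
            raise ValueError("the three-sample scenario takes two coefficients")
        if len(alpha_tildes) == 1:
            alpha_tildes = alpha_tildes * 2
        child_a, child_b = ss.spawn(2)
        t1, s1 = generate_precision(p, alpha_tildes[0], np.random.default_rng(child_a))
        t2, s2 = generate_precision(p, alpha_tildes[1], np.random.default_rng(child_b))
        t3 = coeffs[0] * t1 + coeffs[1] * t2
        s3 = s1 | s2
        return SparseGroundTruth(
            [t1, t2, t3], [s1, s2, s3],
            alpha_tildes, "three_sample_linear", coeffs, seed,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def sample_groups(
    truth: SparseGroundTruth,
    group_sizes: int | list[int],
    seed: int,
) -> GroupDataset:
    """Draw i.i.d. N(0, Theta0[k]^-1) samples for every group.

    Each group uses an independent substream of ``seed``, so the draw is
    reproducible and groups stay independent.
    """
    if np.isscalar(group_sizes):
        group_sizes = [int(group_sizes)] * truth.n_groups
    if len(group_sizes) != truth.n_groups:
        raise ValueError("one sample size per group is required")
    children = _as_seedseq(seed).spawn(truth.n_groups)
    obs = []
    for theta, n_k, child in zip(truth.precisions, group_sizes, children):
        if n_k < 2:
            raise ValueError(f"group size {n_k} < 2")
        eigval, eigvec = np.linalg.eigh(theta)
        if eigval[0] <= 0:
            raise ValueError("precision matrix is not positive definite")
        rng = np.random.default_rng(child)
        z = rng.standard_normal((n_k, theta.shape[0]))
        # covariance root: Theta^-1 = V diag(1/d) V^T, so X = Z diag(d^-1/2) V^T
        obs.append((z / np.sqrt(eigval)) @ eigvec.T)
    return GroupDataset(observations=obs)
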