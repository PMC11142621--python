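import numpy as np
import pytest

from fglinfer import AdmmOptions, CovarianceSet


@pytest.fixture
def tight_opts() -> AdmmOptions:
    """Solver options tight enough for 1e-5-level comparisons."""
    return AdmmOptions(tol_primal=1e-8, tol_dual=1e-8, max_iter=20000)


@pytest.fixture
def random_cov_pair() -> CovarianceSet:
    """Two well-conditioned 5x5 sample correlation matrices, n=60 each."""
    rng = np.random.default_rng(42)
    mats = []
    for _ in range(2):
        x = rng.standard_normal((60, 5))
        mats.append(np.corrcoef(x, rowvar=False))
    return CovarianceSet(np.stack(mats), [60, 60])
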