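import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import montinv as mv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> mv.SimulationConfig:
    return mv.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def pool(default_config) -> list:
    return mv.simulate_pool(default_config)


@pytest.fixture(scope="session")
def backbone(default_config) -> mv.Phylogeny:
    return mv.simulate_backbone(default_config)


@pytest.fixture(scope="session")
def landscape(default_config) -> mv.LandscapeGrid:
    return mv.simulate_landscape(default_config)


@pytest.fixture(scope="session")
def toy_tree() -> mv.Phylogeny:
    """((a:1,b:1):1,c:2); -- MPD(a,b,c)=10/3, MNTD=8/3."""
    return mv.read_newick("((a:1,b:1):1,c:2);")


def nodf_oracle(A: np.ndarray) -> float:
    """Independent direct evaluation of the NODF pairwise definition."""
    A = np.asarray(A)
    r, c = A.shape
    total = 0.0
    for axis in (0, 1):
        M = A if axis == 0 else A.T
        n = M.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                fi, fj = M[i].sum(), M[j].sum()
                if fi > fj and fj > 0:
                    shared = int(np.logical_and(M[i], M[j]).sum())
                    total += 100.0 * shared / fj
    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return total / n_pairs
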