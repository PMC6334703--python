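import pytest

from ttocapi import TTOParams, default_project


def brute_force_indifference(u_star, l=10.0, t=10.0, step=0.5):
    """Independent oracle: linear scan over every presentable Life A
    duration, returning the grid point whose utility (computed inline as
    (a - l)/t) is closest to the true utility."""
    n = int(round((l + t) / step))
    grid = [round(i * step, 10) for i in range(n + 1)]
    return min(grid, key=lambda a: abs((a - l) / t - u_star))


@pytest.fixture
def params():
    return TTOParams()


@pytest.fixture(scope="session")
def project():
    return default_project()
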