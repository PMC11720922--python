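import ctypes
import gc

import numpy as np
import pandas as pd
import pytest

from cbnn import SurvivalDataset


def trim_memory() -> None:
    """Release freed allocator arenas back to the OS.

    The large person-moment tables churn hundreds of MB per fit; without an
    explicit trim, glibc keeps the freed arenas and the test process's
    resident size ratchets up across tests.
    """
    gc.collect()
    try:
        ctypes.CDLL("libc.so.6").malloc_trim(0)
    except OSError:  # non-glibc platform
        pass


@pytest.fixture(autouse=True)
def _trim_after_test():
    yield
    trim_memory()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_exponential_data(
    n: int,
    rate: float = 0.5,
    censor_frac: float = 0.0,
    rng: np.random.Generator | None = None,
    p: int = 1,
) -> SurvivalDataset:
    """Exponential survival data with independent standard-normal covariates.

    Covariates do not affect the hazard; useful for null-model checks and
    closed-form limits.
    """
    rng = np.random.default_rng(rng)
    times = rng.exponential(1.0 / rate, size=n)
    event = np.ones(n)
    if censor_frac > 0:
        cens = rng.uniform(size=n) < censor_frac
        times[cens] = rng.uniform(0, times[cens])
        event[cens] = 0.0
    cov = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
    )
    return SurvivalDataset(time=times, event=event, covariates=cov)


def random_toy_dataset(rng: np.random.Generator, n_max: int = 20) -> SurvivalDataset:
    """Small random survival dataset with censoring and distinct times."""
    n = int(rng.integers(4, n_max + 1))
    times = np.sort(rng.uniform(0.2, 10.0, size=n))
    times += np.linspace(0, 1e-3, n)  # keep times distinct
    event = rng.integers(0, 2, size=n).astype(float)
    if event.sum() == 0:
        event[int(rng.integers(0, n))] = 1.0
    cov = pd.DataFrame({"x0": rng.normal(size=n)})
    return SurvivalDataset(time=times, event=event, covariates=cov)
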