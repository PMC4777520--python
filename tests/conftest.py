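"""Shared fixtures: scaled-down phantoms and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from msiseg.io import default_peak_list
from msiseg.phantom import PhantomSpec, generate_phantom_series
from msiseg.preprocess import run_preprocessing


def small_spec(**overrides) -> PhantomSpec:
    """A 3-time-point, 40x20 phantom with proportionally scaled geometry."""
    kw = dict(
        n_time_points=3,
        grid_shape=(40, 20),
        seed_center=(20.0, 10.0),
        seed_axes=(18.0, 8.0),
        endosperm_center=(25.0, 10.0),
        endosperm_axes=(11.0, 5.5),
        embryo_center=(8.0, 10.0),
        embryo_axes_start=(3.0, 2.0),
        embryo_growth=(0.5, 0.25),
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def peaks():
    return default_peak_list()


@pytest.fixture(scope="session")
def small_series():
    return generate_phantom_series(small_spec(), seed=11)


@pytest.fixture(scope="session")
def small_result(small_series, peaks):
    datasets, _truth = small_series
    return run_preprocessing(datasets, peaks)


@pytest.fixture(scope="session")
def small_profiles(small_result):
    return small_result.profiles


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_best_lag(spectrum: np.ndarray, reference: np.ndarray,
                         max_lag: int) -> int:
    """Exhaustive lag scan with the same tie rule as the FFT path.

    Score of lag λ: overlap dot product of the spectrum shifted by +λ bins
    against the reference. Ties resolve to smallest |λ|, negative first.
    """
    s = np.asarray(spectrum, dtype=float)
    r = np.asarray(reference, dtype=float)
    n = len(s)
    best_lag, best_val = 0, -np.inf
    order = [0]
    for k in range(1, max_lag + 1):
        order.extend((-k, k))
    for lam in order:
        if lam >= 0:
            val = float(np.dot(s[:n - lam], r[lam:])) if lam < n else 0.0
        else:
            val = float(np.dot(s[-lam:], r[:n + lam])) if -lam < n else 0.0
        if val > best_val:
            best_val, best_lag = val, lam
    return best_lag


def exhaustive_leaf_bmu(model, x: np.ndarray) -> int:
    """Nearest leaf by cosine distance, scanning every outermost-ring node."""
    from msiseg.h2som import cosine_distance

    lattice = model.lattice
    leaves = lattice.ring_ids(lattice.n_rings)
    dists = [cosine_distance(model.prototypes[i], x) for i in leaves]
    return int(leaves[int(np.argmin(dists))])
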