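"""Shared fixtures: small rendered scene sets and analytic feature tables."""

import numpy as np
import pytest

from spadvi import indices as vi
from spadvi import synthscene as sy


@pytest.fixture(scope="session")
def spectral_model():
    return sy.SpectralModel()


@pytest.fixture(scope="session")
def small_cfg():
    """Four shade levels, 6 seedlings each — enough for mask statistics."""
    return sy.ShadeConfig(n_per_level=6)


@pytest.fixture(scope="session")
def small_scenes(small_cfg, spectral_model):
    records = sy.sample_population(small_cfg, noise_sd=1.0, seed=11)
    return sy.render_population(records, spectral_model, small_cfg, seed=12)


@pytest.fixture(scope="session")
def feature_table(small_scenes):
    return vi.feature_table_from_scenes(small_scenes)


@pytest.fixture(scope="session")
def analytic_table():
    """Band-mean feature table with canopy-scale noise (study-like regime)."""
    cfg = sy.ShadeConfig()
    base = sy.simulate_feature_table(cfg, seed=21)
    return vi.feature_table_from_band_means(base)


def kapur_bruteforce(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent exhaustive maximum-entropy threshold (loop-based oracle)."""
    lo, hi = values.min(), values.max()
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    entropies = {}
    for t in range(1, n_bins):
        p0 = p[:t].sum()
        p1 = p[t:].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        h = 0.0
        for q, mass in ((p[:t], p0), (p[t:], p1)):
            for pi in q:
                if pi > 0:
                    h -= (pi / mass) * np.log(pi / mass)
        entropies[t] = h
    hmax = max(entropies.values())
    # smallest cut among (floating-point) ties, as cuts through empty bins
    # share the same class entropies
    best_t = min(t for t, h in entropies.items()
                 if h >= hmax - 1e-9 * max(abs(hmax), 1.0))
    return float(edges[best_t])
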