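import numpy as np
import pytest

from cohesion_delim import sdm, synthetic_data as syn


@pytest.fixture(scope="session")
def small_stack():
    """3-layer autocorrelated 50x50 stack."""
    return syn.simulate_climate_stack(3, (50, 50), autocorr_length=5, seed=11)


@pytest.fixture(scope="session")
def shared_niche():
    return syn.NicheParams(optima=[0.8, 0.8, 0.0], tolerances=[0.6, 0.6, 1.5])


@pytest.fixture(scope="session")
def null_occurrences(small_stack, shared_niche):
    """Two lineages drawn from one niche (the ecological-interchangeability null)."""
    return syn.simulate_occurrences(
        small_stack, {"A": shared_niche, "B": shared_niche}, {"A": 40, "B": 55}, seed=12
    )


@pytest.fixture(scope="session")
def fast_config():
    """Single-candidate config for tests that do not exercise selection."""
    return sdm.FitConfig(fc_grid=["LQ"], rm_grid=[1.0])


@pytest.fixture(scope="session")
def fitted_null_pair(small_stack, null_occurrences, fast_config):
    """Thinned occurrences, models, and surfaces for the null pair (shared bg)."""
    bg = sdm.sample_background(small_stack, small_stack.n_valid, seed=13)
    out = {}
    for lab, occ in null_occurrences.items():
        thin = sdm.thin_occurrences(occ, small_stack)
        model, surface, _ = sdm.fit_sdm(thin, small_stack, fast_config, background_cells=bg)
        out[lab] = (thin, model, surface)
    return out


@pytest.fixture(scope="session")
def uniform_surface(small_stack):
    from cohesion_delim.sdm import SuitabilitySurface

    c = small_stack.n_valid
    raw = np.full(small_stack.shape, 1.0 / c)
    return SuitabilitySurface(
        raw=raw, logistic=np.full(small_stack.shape, 0.5), mask=small_stack.mask.copy()
    )


def random_surface(stack, seed):
    """Random normalized suitability surface on a stack's grid."""
    from cohesion_delim.sdm import SuitabilitySurface

    rng = np.random.default_rng(seed)
    raw = np.where(stack.mask, rng.random(stack.shape), np.nan)
    raw = raw / np.nansum(raw)
    logistic = raw / np.nanmax(raw)
    return SuitabilitySurface(raw=raw, logistic=logistic, mask=stack.mask.copy())
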