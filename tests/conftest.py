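import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

import cddsev as cs


@pytest.fixture(scope="session")
def model():
    return cs.default_cdd_model()


@pytest.fixture(scope="session")
def study_cohort():
    """206-subject bounded cohort with study-like missingness + retest rows."""
    cfg = cs.GeneratorConfig(n_subjects=206, seed=42)
    cohort = cs.generate_cohort(cfg)
    return cs.generate_retest_pairs(cohort, cfg), cfg


@pytest.fixture(scope="session")
def complete_latent_cohort():
    """Complete-data cohort on the latent-linear scale (no clipping)."""
    cfg = cs.GeneratorConfig(n_subjects=400, seed=7, bounded=False,
                             missing_rates={})
    return cs.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def fitted_complete(model, complete_latent_cohort):
    cohort, _ = complete_latent_cohort
    harm = cs.filter_inclusion(cohort)
    fit = cs.fit_sem(model, harm)
    return harm, fit


def random_missing_mask(rng: np.random.Generator, n: int, p: int,
                        rate: float = 0.3) -> np.ndarray:
    """Random mask keeping at least one observed cell per row."""
    mask = rng.random((n, p)) < rate
    for i in range(n):
        if mask[i].all():
            mask[i, rng.integers(p)] = False
    return mask
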