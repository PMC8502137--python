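import numpy as np
import pytest

from gcsubtype.resources import load_reference_signatures
from gcsubtype.simulate import CohortTruth, default_profiles, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return load_reference_signatures()


def small_truth(seed: int = 0, n: int = 24) -> CohortTruth:
    """A reduced cohort (fewer samples, lighter mutation burden) for unit
    tests; the full default conditions are exercised by the acceptance
    suite."""
    profiles = default_profiles()
    for p in profiles:
        p.tmb_mean /= 4
    return CohortTruth(n_samples=n, seed=seed, profiles=profiles)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_truth(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study conditions (70 samples)."""
    return generate_cohort(CohortTruth(seed=0))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Full pipeline run on the default cohort, shared across tests."""
    from gcsubtype.pipeline import run_pipeline

    return run_pipeline(default_cohort.mutations, default_cohort.segments,
                        default_cohort.hla)


def mixture_catalog(rng: np.random.Generator, reference, n_samples=70,
                    muts_per_sample=500, mixtures=None):
    """Catalog drawn from planted signature mixtures (no cohort overhead)."""
    from gcsubtype.signatures import MutationalCatalog

    k = reference.matrix.shape[1]
    counts = np.zeros((n_samples, 96), dtype=np.int64)
    mix_rows = []
    for i in range(n_samples):
        mix = mixtures[i % len(mixtures)] if mixtures is not None else rng.dirichlet(np.full(k, 0.7))
        mix_rows.append(mix)
        p = reference.matrix @ mix
        counts[i] = rng.multinomial(muts_per_sample, p)
    catalog = MutationalCatalog(samples=[f"S{i:03d}" for i in range(n_samples)],
                                counts=counts)
    return catalog, np.array(mix_rows)
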