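import numpy as np
import pytest

from methconcord.synth import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal: 19 subjects, 4 tissues, 3000 probes."""
    cfg = SimulationConfig(n_subjects=19, n_probes=3000, frac_correlated=0.0,
                           noise_sd=0.02, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """15% of probes share cross-tissue subject deviations at rho 0.7."""
    cfg = SimulationConfig(n_subjects=19, n_probes=8000, frac_correlated=0.15,
                           rho_true=0.7, noise_sd=0.0, seed=202)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def snp_cohort():
    """Planted 2-/3-cluster genotype probes."""
    cfg = SimulationConfig(n_subjects=19, n_probes=800, frac_snp2=0.15,
                           frac_snp3=0.15, allele_freq=0.5, noise_sd=0.02,
                           snp_noise_sd=0.02, seed=303)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
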