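import numpy as np
import pytest

from ilsweep import AncestralDemographyX, GenerationDemography, ScaledDemography


@pytest.fixture
def rng():
    return np.random.default_rng(20150814)


@pytest.fixture(scope="session")
def gen_demog():
    """Generation-unit demography of the HC ancestor (package defaults)."""
    return GenerationDemography()


@pytest.fixture(scope="session")
def scaled_demog():
    """Mutation-scaled demography with the published Δτ and θ."""
    return ScaledDemography(
        tau_hc=0.005, tau_hcg=0.005 + 0.002468, theta_hc=0.003232, theta_hcg=0.003232
    )


@pytest.fixture(scope="session")
def small_sweep_demog():
    """Scaled-down ancestral population for fast sweep simulations.

    n_chrom = 3000 and an inter-speciation interval of 3000 generations, so
    the neutral ILS level is 2/3 * exp(-1).
    """
    return AncestralDemographyX(
        Ne=2000.0,
        t_hc_years=1_000_000.0,
        t_hcg_years=1_000_000.0 + 3000 * 20.0,
        segment_genetic_length_cm=2.0,
    )
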