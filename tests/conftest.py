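import numpy as np
import pytest

from para2cycle import default_rates


@pytest.fixture(scope="session")
def rates():
    """Wild-type rate set shared across the suite."""
    return default_rates()


@pytest.fixture(scope="session")
def binding_only_rates(rates):
    """Reversible nucleotide binding only (the closed-form testbed)."""
    return rates.replace(
        k1=1.0, k_minus1=8.0, k2=0.0, k5=0.0, k_minus5=0.0, kcat=0.0, k4=0.0,
        k6_adp_to_atp=0.0, k6_adp_to_adp=0.0, k6_atp_to_atp=0.0, k_star_relax=0.0,
    )


@pytest.fixture(scope="session")
def pde_default_run():
    """One default-parameter tug-of-war run shared by the oscillation tests."""
    from para2cycle.spatial import SpatialConfig, simulate_cell

    return simulate_cell(SpatialConfig(t_end_s=2500.0))


def make_kymograph(t, density, length_um=2.0):
    """Synthetic kymograph helper for metric tests."""
    from para2cycle.spatial import Kymograph

    density = np.asarray(density, float)
    n = density.shape[1]
    x = (np.arange(n) + 0.5) * (length_um / n)
    total = density.sum(axis=1)
    return Kymograph(np.asarray(t, float), density, x, total, (0.5,))
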