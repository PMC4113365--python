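import numpy as np
import pytest

from alloscale import EEDataset, PowerLaw, SimulationConfig, generate_cohort
from alloscale.fixtures import mouse5_model


@pytest.fixture(scope="session")
def mouse5():
    """Reconstructed five-organ mouse REE model (gram units)."""
    return mouse5_model()


@pytest.fixture(scope="session")
def mouse_cohort():
    """One noisy mouse-scale cohort: c=60.6, k=0.69 (kg), 25-35 g, 5% CV, n=100."""
    cfg = SimulationConfig(
        true_c=60.6, true_k=0.69, mass_unit="kg",
        m_lo=0.025, m_hi=0.035, noise_cv=0.05, n=100, reps=1, seed=1,
    )
    return generate_cohort(cfg, 0)


@pytest.fixture()
def exact_power_data():
    """Noise-free allometric dataset (grams)."""
    p = PowerLaw(c=0.5, k=0.7, mass_unit="g")
    mass = np.linspace(20.0, 40.0, 25)
    return EEDataset(mass=mass, ee=p.predict(mass), mass_unit="g"), p
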