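import numpy as np
import pytest

from caplung.cli_io import load_preset
from caplung.models import BaseModelParams, TherapyParams


@pytest.fixture(scope="session")
def preset():
    return load_preset("paper2023")


@pytest.fixture(scope="session")
def kpreset():
    return load_preset("paper2023-kmodel")


@pytest.fixture(scope="session")
def mild_therapy():
    """Synthetic non-stiff therapy scenario where treatment matters.

    Unlike the printed preset (whose metastatic pool is extinct before the
    treatment delay), this configuration keeps P active over a 10-day
    horizon so the optimal-control problem is non-degenerate.
    """
    base = BaseModelParams(
        lam=0.25, K=2000.0, mu=4e-4, gamma=9e-4, delta=0.02,
        beta1=2e-5, beta2=2e-5, beta3=2e-5,
        phi1=0.2, phi2=1e-5, phi3=0.1, I_baseline=100.0, alpha=1.0,
    )
    return TherapyParams(base=base, eps1=1e-3, eps2=1e-3, eps3=0.5, eps4=0.1, tau=1.0)


@pytest.fixture(scope="session")
def mild_dosing():
    """Synthetic scenario with a smooth dosage -> N(t_f) response for PID tests.

    Metastatic suppression of N is nearly off (mu tiny), so clearing P
    with treatment releases N: the dosage response is smooth and
    monotone increasing over the explored range.
    """
    base = BaseModelParams(
        lam=0.25, K=2000.0, mu=1e-6, gamma=9e-4, delta=0.02,
        beta1=2e-5, beta2=2e-5, beta3=2e-5,
        phi1=0.2, phi2=1e-5, phi3=0.1, I_baseline=100.0, alpha=1.0,
    )
    return TherapyParams(base=base, eps1=2e-3, eps2=0.0, eps3=0.2, eps4=0.1, tau=1.0)


@pytest.fixture(scope="session")
def mild_initial():
    return np.array([1000.0, 200.0, 50.0, 0.0])
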