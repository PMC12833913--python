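import numpy as np
import pytest

from qmapsr import phantom as ph
from qmapsr.pipeline import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded 128-grid phantom with three WMH lesions."""
    return ph.make_phantom("fix-1", 42, n_lesions=3, lesion_classes=("WMH",),
                           grid=128)


@pytest.fixture(scope="session")
def small_maps(small_phantom):
    """(T1, T2, PD) maps sampled from the session phantom."""
    return ph.sample_quant_maps(small_phantom, 43)


@pytest.fixture(scope="session")
def desk_report():
    """The full desk-scale experiment (simulate -> train -> evaluate),
    run once and shared by the end-to-end property tests."""
    return run_experiment(ExperimentConfig(seed=0))


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
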