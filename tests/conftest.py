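import numpy as np
import pytest

from longcontrast.regression import fit_gene_regression
from longcontrast.simulate import SimulationConfig, generate_parametric


@pytest.fixture
def worked_fit():
    """The 4-point fit used throughout: slope 0.5, intercept 0.75, R^2 0.5."""
    return fit_gene_regression(np.array([1.0, 0.5, 2.5, 2.0]), np.array([0.0, 1.0, 2.0, 3.0]))


@pytest.fixture
def small_design():
    """A compact synthetic study with a few planted signal genes."""
    config = SimulationConfig(
        n1=10, n2=12, m=25, noise_sd=0.5, signal_genes=frozenset({0, 1, 2}), seed=42
    )
    design, truth, raw = generate_parametric(config)
    return design, truth, raw


def random_fit(rng, n_min=5, n_max=30):
    """A non-degenerate fit on random data (used as a calibration input)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        a = rng.uniform(0.0, 16.0, size=n)
        y = rng.normal(0.0, 1.0, size=n) + rng.normal() * a + rng.normal()
        fit = fit_gene_regression(y, a)
        if not fit.degenerate and fit.r_squared > 1e-6:
            return fit
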