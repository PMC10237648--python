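import warnings

import numpy as np
import pytest

from snapinfer.dataset import SnapshotDataset
from snapinfer.experiments import default_cancer_prior
from snapinfer.models import (CancerGrowthModel, GaussianError, NLMEModel,
                              NormalComponent, PointMass, PopulationModel,
                              TimeSeriesModel, get_model)

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def table1_csv(tmp_path):
    """Small long-format tumour-volume CSV (two patients, irregular times)."""
    path = tmp_path / "tumour.csv"
    path.write_text(
        "ID,Time,Observable,Value\n"
        "1,1.5,tumour_volume,11.00\n"
        "2,1.5,tumour_volume,8.30\n"
        "1,2.1,tumour_volume,11.52\n"
        "3,2.1,tumour_volume,9.80\n"
        "1,4,tumour_volume,12.03\n"
        "2,4,tumour_volume,8.50\n"
    )
    return path


@pytest.fixture
def cancer_model():
    return get_model("cancer")


@pytest.fixture
def cancer_prior():
    return default_cancer_prior()


@pytest.fixture
def small_cancer_data():
    from snapinfer.synthetic import generate_cancer

    return generate_cancer(seed=7, n_per_time=5)  # N = 30


class ConstantOutputModel(TimeSeriesModel):
    """y(psi, t) = psi[0] for every t: the linear-Gaussian toy dynamics."""

    n_parameters = 1
    n_observables = 1
    parameter_names = ["level"]
    observable_names = ["value"]

    def simulate_batch(self, psis, times):
        psis = np.atleast_2d(np.asarray(psis, float))
        self.n_evaluations += len(psis)
        out = np.repeat(psis[:, :1], len(times), axis=1)
        return out[:, :, None]

    def simulate_batch_with_sensitivities(self, psis, times, wrt=None):
        out = self.simulate_batch(psis, times)
        if wrt is None:
            wrt = [0]
        sens = np.zeros((len(out), len(times), 1, len(wrt)))
        for a, k in enumerate(wrt):
            if k == 0:
                sens[:, :, 0, a] = 1.0
        return out, sens


@pytest.fixture
def linear_gaussian_model():
    """y = psi + eps with psi ~ N(mu, sigma_p^2), eps ~ N(0, sigma^2)."""
    pop = PopulationModel([NormalComponent("level"), PointMass("sigma")])
    return NLMEModel(ConstantOutputModel(), GaussianError(), pop,
                     name="linear-gaussian")


def finite_difference_gradient(f, x, h=1e-6):
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for k in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        g[k] = (f(xp) - f(xm)) / (2 * h)
    return g
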