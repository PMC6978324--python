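import numpy as np
import pytest

from thrombin_msm.embedding import embed_latent_to_structures, toy_template
from thrombin_msm.synthetic_dynamics import PotentialSpec, simulate_overdamped


@pytest.fixture(scope="session")
def spec():
    return PotentialSpec()


@pytest.fixture(scope="session")
def deep_spec():
    return PotentialSpec(well_depths=(4.5, 5.0), barrier_height=4.0)


@pytest.fixture(scope="session")
def template():
    return toy_template()


@pytest.fixture(scope="session")
def small_ensemble(spec, template):
    """500-frame embedded trajectory in the sodium-on condition."""
    latent = simulate_overdamped(spec, 1, 499, dt=5e-3, seed=42, start=spec.well_E_center)
    return embed_latent_to_structures(latent, template)


@pytest.fixture(scope="session")
def random_rotation():
    def make(seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        return Q

    return make
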