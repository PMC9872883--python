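import numpy as np
import pytest

from mmtomo.core import AnisotropyParams
from mmtomo.maps import layered_anisotropy
from mmtomo.phantom import adenoma_spec, carcinoma_spec, generate_cohort, generate_phantom
from mmtomo.stats import moments


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


def random_params(rng, max_retardance=0.9 * np.pi, max_dichroism=0.4):
    """Parameter set inside the principal-branch domain: the total phase
    rotation sqrt(Φ0,90² + Φ45,135² + Φ⊗,⊕²) stays below π, so the matrix
    logarithm recovers the generator exactly."""
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    phases = u * rng.uniform(0, max_retardance)
    deltas = rng.uniform(-max_dichroism, max_dichroism, 3)
    return AnisotropyParams(*phases, *deltas)


@pytest.fixture(scope="session")
def small_adenoma():
    """One 48x48 adenoma phantom at the reference plane."""
    return generate_phantom(adenoma_spec(seed=7, shape=(48, 48)))


@pytest.fixture(scope="session")
def pure_phantom_64():
    """Non-depolarizing 64x64 phantom for coherent (holographic) closure."""
    return generate_phantom(adenoma_spec(seed=3, shape=(64, 64), lambda_target=0.0))


def _cohort_feature(cohort, observable, order):
    out = []
    for ph in cohort:
        ms = layered_anisotropy(ph.mueller[0.6], 0.6)
        out.append(moments(ms.observable(observable), ms.valid)[order])
    return np.array(out)


@pytest.fixture(scope="session")
def acceptance_cohorts():
    """The frozen study conditions: 26 phantoms per class at 128x128,
    seeds 1..26 (adenoma) and 101..126 (carcinoma), analysis plane 0.6 rad.

    Shared session-wide because generation dominates the suite's runtime.
    """
    aden = generate_cohort(adenoma_spec(shape=(128, 128)), 26, base_seed=1)
    carc = generate_cohort(carcinoma_spec(shape=(128, 128)), 26, base_seed=101)
    features = {}
    for obs in ("phi_l", "delta_l"):
        for order in (1, 2, 3, 4):
            features[("adenoma", obs, order)] = _cohort_feature(aden, obs, order)
            features[("carcinoma", obs, order)] = _cohort_feature(carc, obs, order)
    return {"adenoma": aden, "carcinoma": carc, "features": features}
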