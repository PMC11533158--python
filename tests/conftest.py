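import numpy as np
import pytest

from starlattice.model import ModelParams, ParticleState, Configuration


@pytest.fixture(scope="session")
def params():
    """Reference model parameters: sigma=1, delta=0.038, theta_pw=0.3, eps=6."""
    return ModelParams(n_particles=2, box_length=20.0)


def facing_pair(r, params, active_i=(True, True, True),
                active_j=(True, True, True), center=(5.0, 5.0)):
    """Two particles on the x axis with patch 0 of each facing the other."""
    cx, cy = center
    pi = ParticleState(np.array([cx, cy]), 0.0, np.array(active_i))
    pj = ParticleState(np.array([cx + r, cy]), np.pi, np.array(active_j))
    return pi, pj


def pair_configuration(r, params, **kw):
    pi, pj = facing_pair(r, params, **kw)
    return Configuration(
        np.array([pi.position, pj.position]),
        np.array([pi.orientation, pj.orientation]),
        np.array([pi.patch_active, pj.patch_active]),
        params, check_overlaps=False)


@pytest.fixture(scope="session")
def flake3():
    from starlattice.synth import honeycomb_flake
    return honeycomb_flake(3)
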