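import numpy as np
import pytest

import atriareg as ar


@pytest.fixture(scope="session")
def spec():
    return ar.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def model(spec):
    return ar.build_phantom(spec)


@pytest.fixture(scope="session")
def geometry():
    """Biplane geometry with offset principal points.

    The image-center triangulation then lands >30 mm from the iso-center
    where the phantom sits: the capture-range condition for the optimizer.
    """
    return ar.make_biplane_geometry(
        principal_offset_a_px=(18.0, 16.0), principal_offset_b_px=(-16.0, 16.0)
    )


@pytest.fixture(scope="session")
def centered_geometry():
    return ar.make_biplane_geometry()


@pytest.fixture(scope="session")
def fullfill(model, spec, geometry):
    """Noise- and artifact-free center injection reaching full fill.

    Returns (sequence, ground truth, index of the fully filled frame).
    """
    scn = ar.center_injection_scenario(noise_sd=0.0, artifacts=False)
    seq, truth = ar.simulate_sequence(model, scn, geometry, seed=1, pv_specs=spec.pv_specs)
    i = int(np.argmax(scn.fill_fractions))
    assert scn.fill_fractions[i] == 1.0
    return seq, truth, i


@pytest.fixture(scope="session")
def fullfill_preps(fullfill):
    seq, _, i = fullfill
    return ar.preprocess_frame(seq, i)


@pytest.fixture(scope="session")
def veinfill(model, spec, geometry):
    """Noise- and artifact-free partial vein injection (peak frame index last)."""
    scn = ar.vein_injection_scenario(noise_sd=0.0, artifacts=False)
    seq, truth = ar.simulate_sequence(model, scn, geometry, seed=2, pv_specs=spec.pv_specs)
    i = int(np.argmax(scn.fill_fractions))
    return seq, truth, i


@pytest.fixture(scope="session")
def veinfill_preps(veinfill):
    seq, _, i = veinfill
    return ar.preprocess_frame(seq, i)
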