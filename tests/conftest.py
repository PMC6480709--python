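"""Shared fixtures: small synthetic plans, deliveries and phantoms.

Everything is generated programmatically with fixed seeds; sizes are kept
small (tens of control points, a few hundred dynalog records, ~15k-voxel
phantoms) so the full suite runs in minutes on one CPU.
"""

import numpy as np
import pytest

from dynaverify import (
    ErrorModel,
    ReconstructionConfig,
    compute_dose,
    make_phantom,
    make_vmat_plan,
    reconstruct,
    simulate_field,
)


@pytest.fixture(scope="session")
def small_plan():
    return make_vmat_plan(cp_count=40)


@pytest.fixture(scope="session")
def wide_plan():
    """Generous, untapered apertures: magnification up to 30 mm never
    clips against the travel range or the opposing bank."""
    return make_vmat_plan(cp_count=40, base_gap_cm=8.0, gap_amplitude_cm=0.5,
                          taper=False)


@pytest.fixture(scope="session")
def zero_error_field(small_plan):
    return simulate_field(small_plan)


@pytest.fixture(scope="session")
def gaussian_field(small_plan):
    return simulate_field(small_plan, ErrorModel("gaussian", sigma_mm=0.5, seed=11))


@pytest.fixture(scope="session")
def wide_gaussian_field(wide_plan):
    return simulate_field(wide_plan, ErrorModel("gaussian", sigma_mm=0.4, seed=3),
                          active_leaves_only=True)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def reference_dose(zero_error_field, phantom):
    beam = reconstruct(zero_error_field, ReconstructionConfig("UR", "expected"),
                       meterset_mu=200.0)
    return compute_dose(beam, phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
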