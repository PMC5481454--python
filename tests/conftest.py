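from __future__ import annotations

import numpy as np
import pytest

import adctexture as at


@pytest.fixture(scope="session")
def glioma_protocol():
    return at.make_protocol("glioma")


@pytest.fixture(scope="session")
def prostate_protocol():
    return at.make_protocol("prostate")


@pytest.fixture()
def small_phantom(glioma_protocol):
    """One deterministic textured phantom (no fluid) on a small grid."""
    spec = at.PhantomSpec(grid_shape=(40, 40, 3),
                          roi_center=(20.0, 20.0, 1.0),
                          roi_radii=(12.0, 10.0, 1.4),
                          adc_mean=1000.0, adc_amplitude=300.0,
                          correlation_length=2.0, seed=42)
    adc, roi = at.generate_adc_phantom(spec, voxel_size=glioma_protocol.voxel_size)
    return spec, adc, roi


@pytest.fixture(scope="session")
def glioma_run():
    """Full 72-ROI glioma one-at-a-time design run, shared across tests.

    The batch emulates the multi-b cohort: heterogeneous texture, SNR and
    adjacent fluid-like structures; native noise sigma = 17.
    """
    specs = at.make_phantom_batch(72, seed=1)
    proto = at.make_protocol("glioma")
    batch = at.simulate_batch(specs, proto, seed=11)
    design = at.ExperimentDesign.glioma()
    table = at.run_design(batch, design, seed=7)
    result = at.all_pairs_tests(table, design)
    return design, table, result
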