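"""Shared fixtures: one reference family, fitted model, phantom and unmixing
result are built once per session and reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from ramangt import image_quant as iq
from ramangt import reference_builder as rb
from ramangt import synthetic_data as sd
from ramangt import unmixing as um
from ramangt.gauche_trans import KineticModel


@pytest.fixture(scope="session")
def reference_family() -> sd.ReferenceFamily:
    return sd.make_reference_family(sd.ReferenceFamilySpec(seed=0))


@pytest.fixture(scope="session")
def fitted_model(reference_family) -> rb.ReferenceModel:
    dataset = rb.ReferenceDataset.from_family(reference_family, preprocess=True)
    return rb.build_reference_model(dataset)


@pytest.fixture(scope="session")
def phantom(fitted_model):
    """Default seeded phantom cube built from the fitted reference model."""
    spec = sd.PhantomSpec(seed=0)
    cube, truth = sd.make_phantom_cube(spec, fitted_model)
    return cube, truth


@pytest.fixture(scope="session")
def unmixed(phantom, fitted_model):
    cube, truth = phantom
    return um.unmix_cube(cube, fitted_model, truth.bg_pixel)


@pytest.fixture(scope="session")
def kinetic_model() -> KineticModel:
    return KineticModel(p=0.15, q=0.8, r=0.26, n=1.0)


@pytest.fixture(scope="session")
def pipeline_result(phantom, fitted_model, kinetic_model):
    cube, truth = phantom
    return iq.run_pipeline(cube, fitted_model, kinetic_model, truth.bg_pixel)
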