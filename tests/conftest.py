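import numpy as np
import pytest
from shapely.geometry import Polygon

from spatimm.regions import RegionAnnotation
from spatimm.synthetic import CohortSpec


@pytest.fixture(scope="session")
def spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def square_annotation() -> RegionAnnotation:
    """A 1 x 1 mm square tumor core centred on a 2 x 2 mm slide."""
    poly = Polygon([(500, 500), (1500, 500), (1500, 1500), (500, 1500)])
    return RegionAnnotation.from_polygon(poly, im_width=100.0)


@pytest.fixture(scope="session")
def blob_patient():
    """One fully generated synthetic patient, shared across read-only tests."""
    from spatimm.synthetic import generate_patient

    return generate_patient(CohortSpec(), np.random.default_rng(7), "patient_fix")
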