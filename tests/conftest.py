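import numpy as np
import pytest
from hypothesis import settings

from metabonet import CohortSpec, generate_cohort, load_atlas

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


TOY_ATLAS_CSV = """abbreviation,name,hemisphere,lobe
A.L,Region A (left),L,Frontal
A.R,Region A (right),R,Frontal
B.L,Region B (left),L,Temporal
B.R,Region B (right),R,Temporal
"""


@pytest.fixture(scope="session")
def aal():
    return load_atlas("aal90")


@pytest.fixture()
def toy_atlas(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text(TOY_ATLAS_CSV)
    return load_atlas(p)


@pytest.fixture(scope="session")
def small_cohort(aal):
    """Three-group cohort small enough for fast end-to-end tests."""
    spec = CohortSpec(n_subjects={"NC": 40, "MCI": 40, "AD": 40}, seed=7)
    return generate_cohort(spec, aal)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
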