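import numpy as np
import pytest

from gqsar.chemistry import ScaffoldTemplate, parse_substituent
from gqsar.modeling import FittedModel

#: The published five-descriptor arylthioindole model, loaded as an external
#: model (identity scaling, wide applicability ranges).
EQ1_NAMES = [
    "R4-HAcceptorCount", "R6-chi2", "R5-slogp",
    "R6-NitrogensCount", "R6-MolecularWeight",
]
EQ1_COEFFS = [0.536788, -0.412083, -0.538397, -0.365145, 0.00256203]
EQ1_INTERCEPT = 4.97922


@pytest.fixture(scope="session")
def eq1_model() -> FittedModel:
    return FittedModel(
        descriptor_names=list(EQ1_NAMES),
        coefficients=np.array(EQ1_COEFFS),
        intercept=EQ1_INTERCEPT,
        n_components=2,
        scaling={n: (0.0, 1.0) for n in EQ1_NAMES},
        training_ranges={n: (-1e9, 1e9) for n in EQ1_NAMES},
    )


@pytest.fixture(scope="session")
def toy_template() -> ScaffoldTemplate:
    """Benzene-like core with two marked sites."""
    return ScaffoldTemplate(smiles="[*:1]c1ccc([*:2])cc1", sites=("R1", "R2"))


@pytest.fixture(scope="session")
def fixture_series():
    from gqsar.synthetic import arylthioindole_fixture
    return arylthioindole_fixture()


def sub(smiles: str, site: str = "R6"):
    return parse_substituent(smiles, site)
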