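import pytest

from lipiderep.rules import AnnotationParams, builtin_rules
from lipiderep.synth import reference_fixture, reference_species


@pytest.fixture(scope="session")
def ref_species():
    return reference_species()


@pytest.fixture(scope="session")
def specs_by_name(ref_species):
    return {s.name: s for s in ref_species}


@pytest.fixture(scope="session")
def ref_fixture():
    """Noise-free simulated spectra + feature table for all 55 species."""
    return reference_fixture()


@pytest.fixture(scope="session")
def rules():
    return builtin_rules()


@pytest.fixture(scope="session")
def ann_params():
    return AnnotationParams()
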