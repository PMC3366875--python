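import pytest

from cdamesh import (
    GeneratorSpec,
    MeshDescriptor,
    MeshThesaurus,
    Qualifier,
    default_config,
    make_cda_set,
    make_mini_mesh,
)

EP = Qualifier("epidemiology", "EP")
DI = Qualifier("diagnosis", "DI")
TH = Qualifier("therapy", "TH")


@pytest.fixture(scope="session")
def clinical_thesaurus() -> MeshThesaurus:
    """Hand-built mini thesaurus with real MeSH descriptors."""
    return MeshThesaurus(
        [
            MeshDescriptor(
                id="D001249",
                preferred_name="Asthma",
                entry_terms=frozenset({"Asthma", "Bronchial Asthma"}),
                tree_numbers=frozenset({"C08.127.108"}),
                allowable_qualifiers=frozenset({EP, DI, TH}),
            ),
            MeshDescriptor(
                id="D006973",
                preferred_name="Hypertension",
                entry_terms=frozenset({"Hypertension", "High Blood Pressure"}),
                tree_numbers=frozenset({"C14.907.489"}),
                allowable_qualifiers=frozenset({EP, DI}),
            ),
            MeshDescriptor(
                id="D003922",
                preferred_name="Diabetes Mellitus, Type 1",
                entry_terms=frozenset(
                    {"Diabetes Mellitus, Type 1", "Juvenile Diabetes"}
                ),
                tree_numbers=frozenset({"C18.452.394.750.124", "C19.246.267"}),
                allowable_qualifiers=frozenset({EP, DI, TH}),
            ),
            MeshDescriptor(
                id="D010406",
                preferred_name="Penicillins",
                entry_terms=frozenset({"Penicillins", "Penicillin"}),
                tree_numbers=frozenset({"D02.065.589.099.750"}),
                allowable_qualifiers=frozenset({TH}),
            ),
            MeshDescriptor(
                id="D010146",
                preferred_name="Pain",
                entry_terms=frozenset({"Pain"}),
                tree_numbers=frozenset({"C23.888.592.612"}),
                allowable_qualifiers=frozenset(),
            ),
            MeshDescriptor(
                id="D049691",  # out of A-G: publication characteristics live in V
                preferred_name="Biography",
                entry_terms=frozenset({"Biography"}),
                tree_numbers=frozenset({"V02.225"}),
                allowable_qualifiers=frozenset(),
            ),
        ]
    )


@pytest.fixture(scope="session")
def gen_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=11)


@pytest.fixture(scope="session")
def mini_mesh(gen_spec):
    return make_mini_mesh(gen_spec)


@pytest.fixture(scope="session")
def cda_set(gen_spec, mini_mesh):
    return make_cda_set(gen_spec, mini_mesh)


@pytest.fixture(scope="session")
def shipped_config():
    return default_config()
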