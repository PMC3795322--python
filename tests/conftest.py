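import pytest

from gocoherence.fixtures import builtin_scenario


@pytest.fixture(scope="session")
def pl22():
    return builtin_scenario("PL22")


@pytest.fixture(scope="session")
def pl3():
    return builtin_scenario("PL3")


@pytest.fixture(scope="session")
def pl4():
    return builtin_scenario("PL4")


@pytest.fixture(scope="session")
def pl8():
    # large background corpus; built once per session
    return builtin_scenario("PL8")


@pytest.fixture(scope="session")
def pl5():
    return builtin_scenario("PL5")


FIG1_OBO = """\
format-version: 1.2

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0030246
name: carbohydrate binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0001871
name: pattern binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0030247
name: polysaccharide binding
namespace: molecular_function
is_a: GO:0030246
is_a: GO:0001871
"""


@pytest.fixture()
def fig1_graph():
    """Binding -> {carbohydrate binding, pattern binding} -> polysaccharide
    binding fragment (a diamond under the aspect root)."""
    from io import StringIO

    from gocoherence.ontology import parse_obo

    return parse_obo(StringIO(FIG1_OBO))
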