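import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from funcphylo import synthetic
from funcphylo.ontology import parse_obo

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


DIAMOND_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000001
alt_id: GO:0099999

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: gone
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture(scope="session")
def diamond_graph():
    """Diamond DAG d -> {b, c} -> root, plus an alt id and an obsolete
    term."""
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def diamond_obo_text():
    return DIAMOND_OBO


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: 12 genomes, ~600-term ontology, planted
    quartet tree, gain/loss 0.05, dirt injected."""
    return synthetic.generate_bundle(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
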