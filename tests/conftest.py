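import pytest

from nsun6kit.recognition import builtin_panels, builtin_rulesets
from nsun6kit.synth import ScaffoldConstraints, generate_scaffold
from nsun6kit.trna import parse_cloverleaf


@pytest.fixture(scope="session")
def thr_cgu_constraints():
    """Wild-type Thr(CGU)-like constraints: U73, C2:G71, C3:G70,
    C11:G24, C12:G23, CCA."""
    return ScaffoldConstraints(anticodon="CGU", seed=20180)


@pytest.fixture(scope="session")
def thr_cgu_record(thr_cgu_constraints):
    return generate_scaffold(thr_cgu_constraints, record_id="Thr(CGU)")


@pytest.fixture(scope="session")
def thr_cgu(thr_cgu_record):
    return parse_cloverleaf(thr_cgu_record)


@pytest.fixture(scope="session")
def rulesets():
    return builtin_rulesets()


@pytest.fixture(scope="session")
def panels():
    return builtin_panels()
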