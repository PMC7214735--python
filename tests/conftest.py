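import pytest

from approvalmeta import reference_corpus
from approvalmeta.simulate import DistSpec, GeneratorConfig, generate


@pytest.fixture(scope="session")
def fixture_corpus():
    return reference_corpus()


@pytest.fixture(scope="session")
def small_corpus():
    """A small censored synthetic corpus exercising every reporting tier."""
    cfg = GeneratorConfig(
        n_approvals=6,
        trials_per_approval=DistSpec.poisson(4.0, minimum=1),
        n_per_arm=DistSpec.fixed(80),
        seed=7,
    )
    return generate(cfg)
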