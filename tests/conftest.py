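import pytest

from srnaforge import (
    FixtureConfig,
    build_panel,
    gen_acceptor,
    gen_target,
    scaffold_registry,
)


@pytest.fixture(scope="session")
def cfg():
    return FixtureConfig(rng_seed=42)


@pytest.fixture(scope="session")
def target(cfg):
    """(mRNA record, annotation) of the synthetic acrA-like target."""
    return gen_target(cfg)


@pytest.fixture(scope="session")
def annotation(target):
    return target[1]


@pytest.fixture(scope="session")
def panel(annotation):
    return build_panel(annotation)


@pytest.fixture(scope="session")
def acceptor(cfg):
    return gen_acceptor(cfg)


@pytest.fixture(scope="session")
def scaffolds():
    return scaffold_registry()
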