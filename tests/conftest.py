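import pytest

from pamcas.grammar import DendrimerSpec, Registry


@pytest.fixture(scope="session")
def registry() -> Registry:
    return Registry.default()


@pytest.fixture(scope="session")
def ab3(registry):
    return registry["AB3"]


@pytest.fixture(scope="session")
def ab6(registry):
    return registry["AB6"]


@pytest.fixture(scope="session")
def make_spec(registry):
    """Build a spec from layer tokens, e.g. make_spec('3', '6', form='ammonium')."""

    def _make(*tokens: str, form: str = "ammonium") -> DendrimerSpec:
        return DendrimerSpec(
            core=registry.core,
            layers=tuple(registry.by_token(t) for t in tokens),
            terminal_form=form,
            cap=registry.cap,
        )

    return _make
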