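import pytest

from yeastyield import ModelVariant, fit_variant, load_packaged_corpus
from yeastyield.corpus import ProductionRecord


@pytest.fixture(scope="session")
def corpus():
    """The packaged literature training corpus."""
    return load_packaged_corpus()


@pytest.fixture(scope="session")
def model1_fit(corpus):
    return fit_variant(corpus, ModelVariant.MODEL1_WITH_PRI)


@pytest.fixture(scope="session")
def model2_fit(corpus):
    return fit_variant(corpus, ModelVariant.MODEL2_NO_PRI)


@pytest.fixture(scope="session")
def model3_fit(corpus):
    return fit_variant(corpus, ModelVariant.MODEL3_ETHANOL_PRIMARY)


def make_record(**overrides):
    """A small valid record with overridable fields."""
    base = dict(
        reference_id="R1",
        product="testol",
        yield_c=0.01,
        pri_substrate=4.0,
        sec_substrate=2.0,
    )
    base.update(overrides)
    return ProductionRecord(**base)
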