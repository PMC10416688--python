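import pytest

from bccqa.extraction import extract_record
from bccqa.segmentation import segment_report
from bccqa.synthetic import GeneratorConfig, generate_corpus, noise_free


def run_pipeline(docs):
    return [extract_record(segment_report(d), d) for d in docs]


@pytest.fixture(scope="session")
def clean_corpus():
    """Unambiguous rendering, ~1,100 lesions."""
    config = noise_free(GeneratorConfig(n_patients=500, seed=42))
    return generate_corpus(config)


@pytest.fixture(scope="session")
def clean_extractions(clean_corpus):
    docs, truths = clean_corpus
    return run_pipeline(docs), truths


@pytest.fixture(scope="session")
def noisy_corpus():
    """Default noise model: mixed dialects, abbreviations, hedging."""
    config = GeneratorConfig(n_patients=500, seed=43)
    return generate_corpus(config)


@pytest.fixture(scope="session")
def noisy_extractions(noisy_corpus):
    docs, truths = noisy_corpus
    return run_pipeline(docs), truths
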