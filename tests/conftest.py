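import pytest

from reprotext.extract import extract_corpus
from reprotext.synth import SynthConfig, generate_corpus, generate_profiles


@pytest.fixture(scope="session")
def noisy_corpus():
    """A default-noise corpus with its sidecar noise log."""
    docs, noise = generate_corpus(SynthConfig(n_docs=80, seed=7), return_noise_log=True)
    return docs, noise


@pytest.fixture(scope="session")
def clean_corpus():
    """A noise- and missingness-free corpus with its latent profiles."""
    cfg = SynthConfig(n_docs=120, seed=3).noiseless()
    return generate_corpus(cfg), generate_profiles(cfg)


@pytest.fixture(scope="session")
def clean_records(clean_corpus):
    docs, _ = clean_corpus
    records, _ = extract_corpus(docs)
    return records
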