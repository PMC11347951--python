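import pytest

from guardamp.synthetic_data import (
    TranscriptomeSimConfig,
    generate_transcriptome,
    reference_proteins,
)


@pytest.fixture(scope="session")
def demo_transcriptome():
    """Small seeded transcript pool with one plant per AMP family plus decoys."""
    config = TranscriptomeSimConfig(n_decoys=20, seed=7)
    transcripts, truth = generate_transcriptome(config)
    return transcripts, truth


@pytest.fixture(scope="session")
def reference_set():
    return reference_proteins()
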