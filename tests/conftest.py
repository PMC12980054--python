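import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clintime.generate import (
    GeneratorConfig,
    NoiseConfig,
    combine_annotators,
    generate_gold_corpus,
    simulate_annotator,
)


@pytest.fixture(scope="session")
def small_gold():
    """Small gold corpus + timeline shared across tests."""
    cfg = GeneratorConfig(n_docs=8, tokens_per_doc_mean=250.0, tokens_per_doc_sd=60.0, seed=7)
    return generate_gold_corpus(cfg)


@pytest.fixture(scope="session")
def clean_pair_corpus(small_gold):
    """Two zero-noise annotators over the small gold corpus."""
    gold, _ = small_gold
    a = simulate_annotator(gold, NoiseConfig.zero(), seed=1, annotator_id="a")
    b = simulate_annotator(gold, NoiseConfig.zero(), seed=2, annotator_id="b")
    return combine_annotators(a, b)
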