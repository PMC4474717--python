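import pytest

from disomcs.pipeline import PipelineConfig, run_train
from disomcs.crf import TrainConfig
from disomcs.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A compact synthetic study used by most integration tests."""
    return generate_corpus(
        SynthConfig(n_families=8, n_homologs=6, length_range=(60, 120), seed=11)
    )


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A CRF trained on the compact corpus (capped iterations for speed)."""
    cfg = PipelineConfig(train_config=TrainConfig(max_iter=80))
    model, log = run_train(
        small_corpus.queries, small_corpus.db, small_corpus.ss, small_corpus.hits, cfg
    )
    return model, log, cfg
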