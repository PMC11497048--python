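import numpy as np
import pytest
from hypothesis import settings

from utrlm import model, tokenizer
from utrlm.pipeline import planted_motif_study

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def vocab3():
    return tokenizer.build_vocabulary(3)


@pytest.fixture(scope="session")
def tiny_cfg(vocab3):
    """2-layer / 2-head / d=32 desk-scale encoder over the 3-mer vocabulary."""
    return model.ModelConfig.tiny(vocab_size=len(vocab3), max_positions=64)


@pytest.fixture(scope="session")
def tiny_params(tiny_cfg):
    return model.init_params(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def study_result():
    """The scaled-down planted-motif study, trained once per session.

    200-sequence pre-train corpus, 300 MLM steps, fine-tuning on
    150 positive / 300 negative 100-nt windows with UGUAUAU planted in
    90% of positives; shared by the end-to-end tests.
    """
    return planted_motif_study(seed=1)
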