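import logging

import numpy as np
import pytest

from traitlens.synthetic import SyntheticSpec, generate
from traitlens.windowing import Transcript, WindowConfig

# segment() truncation warnings are expected on long synthetic transcripts
logging.getLogger("traitlens.windowing").setLevel(logging.ERROR)


MICRO_WINDOW = WindowConfig(window_size=16, stride=8, max_segments=12, pad_token=0)


def micro_spec(n=30, beta=2.0, sigma_eps=1.0, mode="diffuse", seed=0, **kw):
    """A very small corpus for fast unit tests of the training plumbing."""
    return SyntheticSpec(
        n_transcripts=n,
        words_mean=120.0,
        words_sigma_log=0.2,
        vocab_size=60,
        signal_tokens_per_trait=4,
        base_rate=0.1,
        beta=beta,
        sigma_eps=sigma_eps,
        signal_mode=mode,
        window=MICRO_WINDOW,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def micro_corpus():
    return generate(micro_spec())


@pytest.fixture
def transcript_600():
    return Transcript("t600", np.arange(1, 601, dtype=np.int64), 600)
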