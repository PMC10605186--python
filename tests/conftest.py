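import pytest

from raceseq.align import Aligner
from raceseq.datasets import synthetic_panel


@pytest.fixture(scope="session")
def panel():
    return synthetic_panel()


@pytest.fixture(scope="session")
def aligner(panel):
    return Aligner(panel)


@pytest.fixture(scope="session")
def uniform_weights(panel):
    return {g: 1.0 for g in set(panel.transcriptome.gene.values())}
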