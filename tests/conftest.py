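import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def design_records():
    from semidox import DESIGN_PEPTIDES, SequenceRecord

    return [SequenceRecord(id=k, residues=v) for k, v in DESIGN_PEPTIDES.items()]
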