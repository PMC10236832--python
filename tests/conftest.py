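import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

# two in-frame wild-type coding sequences (16 codons each) shared by the
# end-to-end tests
WT_FOS = "ATGGCTAAACCTGGGTTTCAAGAGCTGATTAAGGCTCGCGAAGAGCAA"
WT_JUN = "ATGTTTGGGCCCAAATTGACCGATCGATTTGCCGCTGAAGATCTGAAG"
CONST_F = "ACGTACGTACGTACGTAC"
CONST_R = "GGCCTTGGCCTTGGCCTT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
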