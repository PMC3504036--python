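import numpy as np
import pytest

from cleavescan import synthcohort
from cleavescan.variantmodel import AmpliconSpec, GeneSpec


@pytest.fixture(scope="session")
def fixtures():
    return synthcohort.make_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20120101)


@pytest.fixture
def family_amplicon():
    """827-bp two-step amplicon with M13 adaptors on a 1476-bp gene."""
    gene = GeneSpec(name="accD", length_bp=1476)
    return AmpliconSpec(
        gene=gene,
        product_length_L=827,
        forward_start=1,
        strand="sense",
        adaptor_len_fwd=19,
        adaptor_len_rev=20,
        label_scheme="M13-two-step",
        name="CA",
    )


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
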