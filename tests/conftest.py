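import numpy as np
import pytest

from irisqtl.kinship import Pedigree, kinship_from_pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_pedigree():
    """Ten-member pedigree with hand-computable kinship coefficients.

    F1 x F2 -> A, B (full sibs); F1 x F3 -> C (half sib of A/B);
    A x F4 -> D (so B is D's uncle/aunt: avuncular);
    A x B  -> E (full-sib mating: E is inbred, phi(E,E) = 0.625).
    """
    return Pedigree(
        [
            ("F1", "NA", "NA", "M", "founder"),
            ("F2", "NA", "NA", "F", "founder"),
            ("F3", "NA", "NA", "F", "founder"),
            ("F4", "NA", "NA", "F", "founder"),
            ("A", "F1", "F2", "M", ""),
            ("B", "F1", "F2", "F", ""),
            ("C", "F1", "F3", "M", ""),
            ("D", "A", "F4", "M", ""),
            ("E", "A", "B", "F", ""),
            ("F5", "NA", "NA", "M", "founder"),
        ]
    )


@pytest.fixture
def hand_kinship(hand_pedigree):
    return kinship_from_pedigree(hand_pedigree)
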