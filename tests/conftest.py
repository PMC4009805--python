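import random

import pytest

from flexitrim import (
    DEFAULT_BARCODES,
    AlignmentAcceptance,
    ScoringScheme,
    TagRole,
    TagSequence,
)


@pytest.fixture
def scoring():
    return ScoringScheme(1, -1, -6)


@pytest.fixture
def barcode_tags():
    return tuple(
        TagSequence(f"bc{i + 1}", seq, TagRole.BARCODE)
        for i, seq in enumerate(DEFAULT_BARCODES)
    )


@pytest.fixture
def barcode_acceptance():
    """Full-length 7-mer overlap with the error-tolerant threshold."""
    return AlignmentAcceptance(min_overlap=7, threshold=2.0)


@pytest.fixture
def rng():
    return random.Random(20120895)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(length))
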