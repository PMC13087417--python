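import numpy as np
import pytest

from nmascope.synthetic_data import (
    EmbeddingSpec,
    TranscriptSpec,
    make_embeddings,
    make_transcript,
)
from nmascope.transcript_saturation import TranscriptModel


@pytest.fixture(scope="session")
def actin_like_model() -> TranscriptModel:
    """375-residue ORF + stop: 1,128 coding nt, 3 exons, plus strand."""
    return make_transcript(TranscriptSpec(n_codons=375, n_exons=3), seed=101)


@pytest.fixture(scope="session")
def tiny_model() -> TranscriptModel:
    """Single-codon ORF (ATG + stop): 6 coding nt, one exon."""
    return make_transcript(
        TranscriptSpec(n_codons=1, n_exons=1, utr5_length=10, utr3_length=10),
        seed=7,
    )


@pytest.fixture(scope="session")
def three_exon_model() -> TranscriptModel:
    """100-codon ORF over three exons; large enough for the 50-nt rule to
    split escape/subject stop gains."""
    return make_transcript(TranscriptSpec(n_codons=100, n_exons=3), seed=13)


@pytest.fixture(scope="session")
def scattered_pool():
    """Mixture of many loosely concentrated clusters used as a control pool."""
    spec = EmbeddingSpec(
        cluster_sizes={f"syn{i:02d}": 12 for i in range(25)},
        n_dims=64,
        concentration=1.5,
    )
    es, _ = make_embeddings(spec, seed=42)
    return es
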