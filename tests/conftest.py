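import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboterm import TranscriptModel
from riboterm.simulate import _SENSE_CODONS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_transcript(
    tid: str = "tx1",
    utr5: int = 10,
    n_codons: int = 10,
    utr3: int = 20,
    seed: int = 0,
    stop: str = "TAA",
) -> TranscriptModel:
    """Random valid transcript: ATG + sense codons + stop, flanked by UTRs.

    ``n_codons`` counts all CDS codons including start and stop, so the CDS
    spans 3 * n_codons nt.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    utr5_seq = "".join(bases[rng.integers(0, 4, utr5)])
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    )
    utr3_seq = "".join(bases[rng.integers(0, 4, utr3)])
    seq = utr5_seq + "ATG" + body + stop + utr3_seq
    model = TranscriptModel(tid, seq, utr5, utr5 + 3 * n_codons)
    model.validate()
    return model


@pytest.fixture
def small_transcript() -> TranscriptModel:
    """60-nt transcript with CDS [10, 40): 10-nt 5'UTR, 30-nt CDS, 20-nt 3'UTR."""
    return make_transcript(utr5=10, n_codons=10, utr3=20, seed=0)


@pytest.fixture
def transcript_300nt_cds() -> TranscriptModel:
    """Transcript with a 300-nt CDS for filter-boundary tests."""
    return make_transcript(utr5=20, n_codons=100, utr3=30, seed=1)
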