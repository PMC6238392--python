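import pytest

from m6atriage.synthetic_data import SimulationConfig, generate_dataset
from m6atriage.transcriptome import TranscriptModel


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset shared by integration tests."""
    return generate_dataset(SimulationConfig(n_transcripts=150, seed=7))


@pytest.fixture
def toy_transcript():
    """60-nt transcript with 10/30/20 geometry and known DRACH content."""
    # UTR5 has GGACT at 2; CDS has TGACT at 20 (A at 22); UTR3 has AAACA at 42
    seq = (
        "CC" + "GGACT" + "CCC"          # UTR5: 10 nt
        + "CCCCCCCCCC" + "TGACT" + "CCCCCCCCCCCCCCC"  # CDS: 30 nt
        + "CC" + "AAACA" + "CCCCCCCCCCCCC"  # UTR3: 20 nt
    )
    return TranscriptModel(
        transcript_id="toy",
        gene_id="toygene",
        sequence=seq,
        utr5_len=10,
        cds_len=30,
        utr3_len=20,
    )
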