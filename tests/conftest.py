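import numpy as np
import pytest

from fragribo import (
    Alignment,
    SimConfig,
    Transcript,
    TranscriptomeModel,
    generate_transcriptome,
)


def alignments_from_sim(sim, sample="s"):
    """Build Alignment objects straight from a simulator truth table."""
    out = []
    for row in sim.truth_alignments.to_dict("records"):
        mapped = bool(row["mapped"])
        out.append(
            Alignment(
                read_id=str(row["read_id"]),
                transcript_id=str(row["transcript_id"]) if mapped else "",
                ref_start=int(row["ref_start"]) if mapped else -1,
                ref_end=int(row["ref_end"]) if mapped else -1,
                read_len=int(row["read_len"]),
                mapped=mapped,
                sample=sample,
            )
        )
    return out


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def model(default_cfg):
    """30 random transcripts, 600-2000 nt, shared across tests."""
    return generate_transcriptome(default_cfg)


@pytest.fixture
def tiny_tx():
    """90 nt transcript with CDS [30, 60) and a UU-rich 3'UTR."""
    rng = np.random.default_rng(42)
    seq = list("".join(rng.choice(list("ACGT"), size=90)))
    seq[30:33] = "ATG"
    seq[57:60] = "TAA"
    return Transcript(id="tx1", seq="".join(seq), cds_start=30, cds_end=60)


@pytest.fixture
def tiny_model(tiny_tx):
    return TranscriptomeModel({tiny_tx.id: tiny_tx})
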