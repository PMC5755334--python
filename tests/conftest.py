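import pytest

from splicescape import SimulationConfig, TranscriptModel, simulate


def make_tx(exons, strand="+", tid="t1", gid="g1", chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=tuple(exons)
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared by read-only tests."""
    return simulate(SimulationConfig(n_genes=120, seed=101))
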