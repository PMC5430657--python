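import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from seedsplice import MapperConfig
from seedsplice.formats_io import Genome, Transcript
from seedsplice.simulate import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def tiny_genome():
    """A 12 nt contig with a two-exon plus-strand transcript (intron (4, 8))."""
    genome = Genome({"c1": "ACGTTTTTACGT"})
    tx = Transcript("gA", "tA1", "c1", "+", [(0, 4), (8, 12)])
    return genome, [tx]


@pytest.fixture(scope="session")
def sim_small():
    """20-gene synthetic genome with 1000 default-error reads (seed 11)."""
    cfg = SimConfig(seed=11, n_genes=20, n_reads=1000)
    genome, transcripts = simulate_genome(cfg)
    reads, truths = simulate_reads(genome, transcripts, cfg)
    return cfg, genome, transcripts, reads, truths


@pytest.fixture(scope="session")
def sim_small_run(sim_small):
    """Annotated pipeline run over the small simulation."""
    from seedsplice.pipeline import run_pipeline

    cfg, genome, transcripts, reads, truths = sim_small
    report, alignments, junctions, quants = run_pipeline(
        genome, transcripts, reads, MapperConfig()
    )
    return report, alignments, junctions, quants


@pytest.fixture(scope="session")
def default_config():
    return MapperConfig()
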