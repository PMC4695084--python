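import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from juncspect.annotation import GeneModel
from juncspect.simulate import SimulationConfig, generate_reference


SAM_HEADER = ["@HD\tVN:1.6\tSO:unsorted"]


def write_sam_text(path, reads, chrom_lengths):
    """Write a minimal SAM file.

    ``reads`` are (qname, flag, chrom, pos1, cigar, nm) tuples; pos1 is
    1-based as in SAM.
    """
    with open(path, "w") as fh:
        fh.write(SAM_HEADER[0] + "\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, chrom, pos1, cigar, nm in reads:
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*\tNM:i:{nm}\n")


@pytest.fixture
def sam_writer(tmp_path):
    def _write(reads, chrom_lengths={"chr1": 100_000}, name="reads.sam"):
        path = tmp_path / name
        write_sam_text(path, reads, chrom_lengths)
        return str(path)

    return _write


@pytest.fixture
def toy_gene():
    # two exons [100,200) and [300,400): one intron [200,300)
    return GeneModel("gA", "chr1", "+", ((100, 200), (300, 400)))


@pytest.fixture(scope="session")
def small_reference():
    """A small deterministic synthetic reference shared across tests."""
    cfg = SimulationConfig(
        n_tissues=4, n_genes=30, seed=42, intron_length_range=(50, 2000),
        depth_per_tissue=30.0,
    )
    genes, index, truth = generate_reference(cfg)
    return cfg, genes, index, truth
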