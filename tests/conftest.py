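import pytest

from escapeseq import readproc, simdata


@pytest.fixture(scope="session")
def tiny_screen(tmp_path_factory):
    """Noise-free tiny synthetic screen: 20 peptides x 3 alleles, 2 replicates."""
    fx = simdata.make_fixture("tiny", seed=3)
    out = tmp_path_factory.mktemp("tiny_screen")
    sim = simdata.simulate_screen(fx["library"], fx["barcodes"], fx["model"],
                                  replicates=2, out_dir=out)
    table = readproc.count_reads(sim.fastq_files, fx["library"],
                                 fx["barcodes"], anchors=fx["anchors"])
    return {**fx, "sim": sim, "table": table}
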