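"""Demultiplexing: anchor extraction, counting, conservation, chimera rate."""

import numpy as np
import pandas as pd
import pytest

from escapeseq import readproc as rp
from escapeseq import simdata
from escapeseq.libdesign import PeptideRecord, AlleleBarcode

ANCH = rp.AnchorSpec()


def make_read(oligo, barcode, anchors=ANCH):
    return (anchors.peptide_flank5 + oligo + anchors.peptide_flank3
            + anchors.barcode_flank5 + barcode + anchors.barcode_flank3)


OLIGO27 = "ATGGCAGCAGCAGCAGCAGCAGCAGCA"   # 27 nt, 9 codons
BARCODE = "TCACAGCCTAAGATAGTAAAGTGGGATAGGGACATG"


class TestExtract:
    def test_constructed_read_extracts(self):
        res = rp.extract_insert(make_read(OLIGO27, BARCODE), ANCH)
        assert res.ok
        assert res.peptide_dna == OLIGO27
        assert res.barcode_dna == BARCODE

    def test_single_mismatch_anchor_discards(self):
        read = make_read(OLIGO27, BARCODE)
        corrupted = "T" + read[1:] if read[0] != "T" else "A" + read[1:]
        res = rp.extract_insert(corrupted, ANCH)
        assert res.reason == "no_anchor"

    def test_duplicated_anchor_discards(self):
        read = ANCH.peptide_flank5 + make_read(OLIGO27, BARCODE)
        assert rp.extract_insert(read, ANCH).reason == "multiple_anchor"

    def test_insert_length_gate(self):
        # 26 nt: not a codon multiple
        res = rp.extract_insert(make_read(OLIGO27[:26], BARCODE), ANCH)
        assert res.reason == "bad_insert_length"
        # 21 nt (7 aa): codon multiple but below the 8-residue floor
        res = rp.extract_insert(make_read(OLIGO27[:21], BARCODE), ANCH)
        assert res.reason == "bad_insert_length"

    def test_corrupted_fraction_oracle(self):
        reads = [make_read(OLIGO27, BARCODE) for _ in range(100)]
        for i in range(10):
            reads[i] = "X" + reads[i][1:]  # break the 5' anchor
        assigned = sum(rp.extract_insert(r, ANCH).ok for r in reads)
        assert assigned == 90

    def test_revcomp_rescue_flag(self):
        from Bio.Seq import Seq
        rc = str(Seq(make_read(OLIGO27, BARCODE)).reverse_complement())
        assert rp.extract_insert(rc, ANCH).reason == "no_anchor"
        assert rp.extract_insert(rc, ANCH, scan_revcomp=True).ok


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture()
def two_construct_library():
    lib = [PeptideRecord(peptide="MAAAAAAAA", source_gene="g1",
                         window_start=1, oligo=OLIGO27),
           PeptideRecord(peptide="MCCCCCCCC", source_gene="g2",
                         window_start=1,
                         oligo="ATGTGCTGCTGCTGCTGCTGCTGCTGC")]
    bcs = [AlleleBarcode("A*01:01", BARCODE),
           AlleleBarcode("B*07:02", "AGCCAGCCGAAAATCGTCAAATGGGACCGCGACATG")]
    return lib, bcs


class TestCountReads:
    def test_known_mixture(self, tmp_path, two_construct_library):
        lib, bcs = two_construct_library
        high = [make_read(lib[0].oligo, bcs[0].barcode_dna)] * 600
        bg = [make_read(lib[1].oligo, bcs[1].barcode_dna)] * 400
        write_fastq(tmp_path / "high.fastq", high)
        write_fastq(tmp_path / "bg.fastq", bg)
        table = rp.count_reads({("high", "R1"): tmp_path / "high.fastq",
                                ("bg", "R1"): tmp_path / "bg.fastq"},
                               lib, bcs)
        c = table.counts.set_index(["peptide", "allele", "bin"])["count"]
        assert c.loc[("MAAAAAAAA", "A*01:01", "high")] == 600
        assert c.loc[("MCCCCCCCC", "B*07:02", "bg")] == 400
        assert table.counts["count"].sum() == 1000

    def test_conservation_per_file(self, tiny_screen):
        for stats in tiny_screen["table"].qc["files"].values():
            assert (stats["n_reads_assigned"] + stats["n_reads_discarded"]
                    == stats["n_reads_total"])

    def test_noise_free_counts_equal_truth(self, tiny_screen):
        truth = simdata.truth_count_table(tiny_screen["sim"].truth)
        key = ["peptide", "allele", "bin", "replicate"]
        a = tiny_screen["table"].counts.sort_values(key).reset_index(drop=True)
        b = truth.sort_values(key).reset_index(drop=True)
        assert (a["count"].to_numpy() == b["count"].to_numpy()).all()

    def test_order_permutation_invariance(self, tmp_path, two_construct_library):
        lib, bcs = two_construct_library
        reads = ([make_read(lib[0].oligo, bcs[0].barcode_dna)] * 5
                 + [make_read(lib[1].oligo, bcs[1].barcode_dna)] * 3)
        write_fastq(tmp_path / "a.fastq", reads)
        write_fastq(tmp_path / "b.fastq", reads[::-1])
        ta = rp.count_reads({("med", "R1"): tmp_path / "a.fastq"}, lib, bcs)
        tb = rp.count_reads({("med", "R1"): tmp_path / "b.fastq"}, lib, bcs)
        pd.testing.assert_frame_equal(ta.counts, tb.counts)

    def test_substituted_barcode_is_discarded(self, tmp_path,
                                              two_construct_library):
        lib, bcs = two_construct_library
        bad_bc = ("G" if BARCODE[0] != "G" else "T") + BARCODE[1:]
        write_fastq(tmp_path / "x.fastq", [make_read(lib[0].oligo, bad_bc)])
        table = rp.count_reads({("low", "R1"): tmp_path / "x.fastq"}, lib, bcs)
        stats = table.qc["files"]["low/R1"]
        assert stats["discard_reasons"]["unknown_barcode"] == 1
        assert table.counts["count"].sum() == 0

    def test_empty_fastq_zero_column(self, tmp_path, two_construct_library):
        lib, bcs = two_construct_library
        (tmp_path / "empty.fastq").write_text("")
        table = rp.count_reads({("bg", "R1"): tmp_path / "empty.fastq"},
                               lib, bcs)
        assert table.qc["files"]["bg/R1"]["n_reads_total"] == 0
        assert (table.counts["count"] == 0).all()

    def test_gzip_input(self, tmp_path, two_construct_library):
        import gzip
        lib, bcs = two_construct_library
        read = make_read(lib[0].oligo, bcs[0].barcode_dna)
        with gzip.open(tmp_path / "z.fastq.gz", "wt") as fh:
            fh.write(f"@r0\n{read}\n+\n{'I' * len(read)}\n")
        table = rp.count_reads({("high", "R1"): tmp_path / "z.fastq.gz"},
                               lib, bcs)
        assert table.counts["count"].sum() == 1


class TestRecombination:
    @staticmethod
    def design():
        return rp.SpikeInDesign(pools={
            "pool1": (frozenset({"A1", "A2"}), frozenset({"p1", "p2"})),
            "pool2": (frozenset({"B1", "B2"}), frozenset({"q1", "q2"})),
        })

    @staticmethod
    def counts(rows):
        return pd.DataFrame(rows, columns=["peptide", "allele", "bin",
                                           "replicate", "count"])

    def test_all_within_pool_is_zero(self):
        df = self.counts([("p1", "A1", "high", "R1", 100),
                          ("q1", "B1", "high", "R1", 100)])
        est = rp.estimate_recombination(df, self.design(), n_panel_alleles=4)
        assert est.raw_cross_fraction == 0.0
        assert est.rate == 0.0

    def test_cross_pool_arithmetic(self):
        df = self.counts([("p1", "A1", "high", "R1", 180),
                          ("p1", "B1", "high", "R1", 20)])
        est = rp.estimate_recombination(df, self.design(), n_panel_alleles=4)
        assert est.raw_cross_fraction == pytest.approx(0.10)
        # 4-allele panel: a uniform swap is detectable 2/3 of the time
        assert est.rate == pytest.approx(0.15)

    def test_overlapping_pools_rejected(self):
        with pytest.raises(rp.DemuxError):
            rp.SpikeInDesign(pools={
                "pool1": (frozenset({"A1"}), frozenset({"p1"})),
                "pool2": (frozenset({"A1"}), frozenset({"q1"}))})

    def test_zero_spikein_reads_errors(self):
        df = self.counts([("other", "A1", "bg", "R1", 50)])
        with pytest.raises(rp.DemuxError):
            rp.estimate_recombination(df, self.design())

    def test_simulated_swap_recovery(self, tmp_path):
        rate = 0.05
        sp = simdata.make_spikein_screen(seed=21, recombination_rate=rate,
                                         reads_per_bin=10_000)
        sim = simdata.simulate_screen(sp["library"], sp["barcodes"],
                                      sp["model"], replicates=1,
                                      out_dir=tmp_path,
                                      constructs=sp["constructs"])
        table = rp.count_reads(sim.fastq_files, sp["library"], sp["barcodes"],
                               anchors=sp["anchors"])
        est = rp.estimate_recombination(table, sp["spikein"])
        # corrected estimate within 3 binomial SE of the injected rate
        detect = 5 / 9
        se = np.sqrt(rate * detect * (1 - rate * detect)
                     / est.n_spikein_reads) / detect
        assert abs(est.rate - rate) < 3 * se
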