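"""Demultiplexing of sorted-bin FASTQ files into a peptide x allele count table.

Reads carry the peptide oligo and the allele barcode between short fixed
cloning anchors.  Extraction requires an exact, unique match of every anchor
(6-10 bp); reads failing any check are discarded with a reason code, never
silently dropped, so assigned + discarded always equals the input.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .libdesign import AlleleBarcode, PeptideRecord

BINS = ("bg", "low", "med", "high")

#: Discard reason codes, in reporting order.
DISCARD_REASONS = (
    "no_anchor", "multiple_anchor", "bad_insert_length",
    "unknown_peptide", "unknown_barcode",
)


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSpec:
    """Fixed flanking sequences around the peptide oligo and allele barcode."""
    peptide_flank5: str = "ACCGGTCA"
    peptide_flank3: str = "GGATCCAT"
    barcode_flank5: str = "GAGCTCAA"
    barcode_flank3: str = "AAGCTTGG"

    def __post_init__(self) -> None:
        anchors = (self.peptide_flank5, self.peptide_flank3,
                   self.barcode_flank5, self.barcode_flank3)
        for a in anchors:
            if not 6 <= len(a) <= 10:
                raise DemuxError(f"anchor {a!r} length outside 6-10 bp")
        if len(set(anchors)) != len(anchors):
            raise DemuxError("anchors must be mutually distinct")


@dataclass
class ExtractResult:
    peptide_dna: str | None = None
    barcode_dna: str | None = None
    reason: str | None = None  # None when assigned

    @property
    def ok(self) -> bool:
        return self.reason is None


def _between(read: str, left: str, right: str, search_from: int = 0
             ) -> tuple[str | None, int, str | None]:
    """Substring strictly between unique exact anchor matches.

    Returns (insert, end_index, reason); reason is set on failure.
    """
    i = read.find(left, search_from)
    if i < 0:
        return None, -1, "no_anchor"
    if read.find(left, i + 1) >= 0:
        return None, -1, "multiple_anchor"
    start = i + len(left)
    j = read.find(right, start)
    if j < 0:
        return None, -1, "no_anchor"
    if read.find(right, j + 1) >= 0:
        return None, -1, "multiple_anchor"
    return read[start:j], j + len(right), None


def extract_insert(read: str, anchors: AnchorSpec,
                   scan_revcomp: bool = False) -> ExtractResult:
    """Extract (peptide_dna, barcode_dna) from one read by exact anchor match.

    The peptide insert must be a multiple of 3 within 24-36 nt (8-12
    residues).  All failures are categorized discards, never exceptions.
    """
    pep, end, reason = _between(read, anchors.peptide_flank5,
                                anchors.peptide_flank3)
    if reason == "no_anchor" and scan_revcomp:
        return extract_insert(str(Seq(read).reverse_complement()), anchors,
                              scan_revcomp=False)
    if reason is not None:
        return ExtractResult(reason=reason)
    if not (24 <= len(pep) <= 36 and len(pep) % 3 == 0):
        return ExtractResult(reason="bad_insert_length")
    bc, _, reason = _between(read, anchors.barcode_flank5,
                             anchors.barcode_flank3, search_from=end)
    if reason is not None:
        return ExtractResult(reason=reason)
    if len(bc) == 0 or len(bc) % 3 != 0:
        return ExtractResult(reason="bad_insert_length")
    return ExtractResult(peptide_dna=pep, barcode_dna=bc)


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path) -> Iterable[str]:
    with _open_maybe_gz(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


@dataclass
class BinCountTable:
    """Read counts per (peptide, allele, bin, replicate) plus per-file QC."""
    counts: pd.DataFrame  # long: peptide, allele, bin, replicate, count
    qc: dict = field(default_factory=dict)

    def pivot(self, replicate: str) -> pd.DataFrame:
        sub = self.counts[self.counts["replicate"] == replicate]
        return sub.pivot_table(index=["peptide", "allele"], columns="bin",
                               values="count", fill_value=0)[list(BINS)]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinCountTable":
        return cls(counts=pd.read_csv(path, sep="\t"))


def count_reads(
    fastq_files: Mapping[tuple[str, str], object],
    library: Sequence[PeptideRecord],
    barcodes: Sequence[AlleleBarcode],
    anchors: AnchorSpec | None = None,
    scan_revcomp: bool = False,
) -> BinCountTable:
    """Demultiplex FASTQ files keyed by (bin, replicate) into a count table.

    Inserts are mapped by exact sequence identity to the designed oligos and
    barcodes; every assigned read increments exactly one cell.  The returned
    table covers the full library x panel grid (zero-filled) and the QC dict
    records totals and discard reasons per file.
    """
    anchors = anchors or AnchorSpec()
    oligo_to_pep = {r.oligo: r.peptide for r in library}
    bc_to_allele = {b.barcode_dna: b.allele for b in barcodes}
    if len(oligo_to_pep) < len({r.peptide for r in library}):
        raise DemuxError("duplicate oligos map to different peptides")

    peptides = sorted({r.peptide for r in library})
    alleles = [b.allele for b in barcodes]
    frames = []
    qc: dict = {"files": {}, "bins": list(BINS)}
    for (bin_name, rep), path in fastq_files.items():
        if bin_name not in BINS:
            raise DemuxError(f"unknown bin {bin_name!r}")
        counter: Counter = Counter()
        reasons: Counter = Counter()
        total = 0
        for seq in iter_reads(path):
            total += 1
            res = extract_insert(seq, anchors, scan_revcomp=scan_revcomp)
            if not res.ok:
                reasons[res.reason] += 1
                continue
            pep = oligo_to_pep.get(res.peptide_dna)
            if pep is None:
                reasons["unknown_peptide"] += 1
                continue
            allele = bc_to_allele.get(res.barcode_dna)
            if allele is None:
                reasons["unknown_barcode"] += 1
                continue
            counter[(pep, allele)] += 1
        discarded = sum(reasons.values())
        qc["files"][f"{bin_name}/{rep}"] = {
            "n_reads_total": total,
            "n_reads_assigned": total - discarded,
            "n_reads_discarded": discarded,
            "discard_reasons": {r: reasons.get(r, 0) for r in DISCARD_REASONS},
        }
        idx = pd.MultiIndex.from_product([peptides, alleles],
                                         names=["peptide", "allele"])
        col = pd.Series(0, index=idx, dtype=int)
        for key, v in counter.items():
            if key in col.index:
                col.loc[key] = v
        frame = col.rename("count").reset_index()
        frame["bin"] = bin_name
        frame["replicate"] = rep
        frames.append(frame)
    counts = pd.concat(frames, ignore_index=True)[
        ["peptide", "allele", "bin", "replicate", "count"]]
    return BinCountTable(counts=counts, qc=qc)


# ---------------------------------------------------------------------------
# recombination (chimera) estimation from spike-in pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeInDesign:
    """Pools of known peptide-allele pairing used to detect barcode swapping.

    Each pool pairs its peptides only with its own alleles; a spike-in
    peptide observed with an allele outside its pool evidences a
    recombination (chimera) event.
    """
    pools: Mapping[str, tuple[frozenset, frozenset]]  # pool -> (alleles, peptides)

    def __post_init__(self) -> None:
        allele_sets = [a for a, _ in self.pools.values()]
        pep_sets = [p for _, p in self.pools.values()]
        for i in range(len(allele_sets)):
            for j in range(i + 1, len(allele_sets)):
                if allele_sets[i] & allele_sets[j]:
                    raise DemuxError("spike-in pools share alleles")
                if pep_sets[i] & pep_sets[j]:
                    raise DemuxError("spike-in pools share peptides")

    def pool_of_peptide(self, peptide: str) -> str | None:
        for name, (_, peps) in self.pools.items():
            if peptide in peps:
                return name
        return None


@dataclass
class RecombinationEstimate:
    rate: float                 # detectability-corrected swap-rate estimate
    raw_cross_fraction: float   # cross-pool reads / total spike-in reads
    n_spikein_reads: int
    per_pool: dict


def estimate_recombination(counts: BinCountTable | pd.DataFrame,
                           spikein: SpikeInDesign,
                           n_panel_alleles: int | None = None,
                           ) -> RecombinationEstimate:
    """Estimate the barcode-swap (chimera) rate from spike-in read counts.

    ``raw_cross_fraction`` is cross-pool spike-in reads over all spike-in
    reads.  Because a swap that lands on an allele of the same pool is
    undetectable, the raw fraction under-reports the swap rate; ``rate``
    divides it by the probability that a uniform swap is detectable,
    (n_panel - n_own_pool) / (n_panel - 1), computed per pool and combined by
    read weight.
    """
    df = counts.counts if isinstance(counts, BinCountTable) else counts
    if n_panel_alleles is None:
        n_panel_alleles = df["allele"].nunique()
    pool_names = list(spikein.pools)
    per_pool = {}
    total = 0
    cross_total = 0
    weighted_detect = 0.0
    for name in pool_names:
        alleles, peptides = spikein.pools[name]
        sub = df[df["peptide"].isin(peptides)]
        n = int(sub["count"].sum())
        cross = int(sub.loc[~sub["allele"].isin(alleles), "count"].sum())
        per_pool[name] = {"n_reads": n, "cross_pool_reads": cross,
                          "cross_fraction": cross / n if n else float("nan")}
        total += n
        cross_total += cross
        if n_panel_alleles > 1:
            weighted_detect += n * (n_panel_alleles - len(alleles)) / (n_panel_alleles - 1)
    if total == 0:
        raise DemuxError("no spike-in reads observed; chimera rate undefined")
    raw = cross_total / total
    detect_prob = weighted_detect / total if total else 1.0
    rate = min(1.0, raw / detect_prob) if detect_prob > 0 else float("nan")
    return RecombinationEstimate(rate=rate, raw_cross_fraction=raw,
                                 n_spikein_reads=total, per_pool=per_pool)
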