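"""Peptide-pool and barcode design for pooled single-chain-trimer (SCT) screens.

Designs three kinds of peptide pools in protein space -- full-protein tiles,
mutation-centred windows and fusion-junction-spanning windows -- encodes them
as DNA oligos with cloning anchors, and designs synonymous-codon barcodes on
the invariant B2M tail that identify the HLA allele of each construct.

Coordinates are 1-based inclusive residue indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .panels import B2M_TAIL_AA

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Most-used human codon per residue (deterministic reverse translation).
HUMAN_PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: Esp3I/BsmBI recognition site (the cloning enzyme) and its reverse complement.
ESP3I_SITE = "CGTCTC"
DEFAULT_FORBIDDEN_SITES: tuple[str, ...] = (ESP3I_SITE, str(Seq(ESP3I_SITE).reverse_complement()))


class DesignError(ValueError):
    """Raised when a library or barcode design request cannot be satisfied."""


class BarcodeCapacityError(DesignError):
    """Synonymous-codon space too small for the requested barcode panel."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DesignError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise DesignError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSpec:
    gene_id: str
    kind: str  # {"point", "inframe_del", "fusion"}
    position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    del_length: int | None = None
    partner_gene_id: str | None = None
    breakpoint_left: int | None = None
    breakpoint_right: int | None = None

    @property
    def tag(self) -> str:
        if self.kind == "point":
            return f"{self.gene_id}:{self.ref_aa}{self.position}{self.alt_aa}"
        if self.kind == "inframe_del":
            end = self.position + self.del_length - 1
            return f"{self.gene_id}:del{self.position}_{end}"
        if self.kind == "fusion":
            return (f"{self.gene_id}::{self.partner_gene_id}"
                    f"@{self.breakpoint_left}|{self.breakpoint_right}")
        raise DesignError(f"unknown variant kind {self.kind!r}")


@dataclass
class PeptideRecord:
    peptide: str
    source_gene: str
    window_start: int  # 1-based inclusive
    variant_tag: str = "WT"
    oligo: str = ""
    flank5: str = ""
    flank3: str = ""

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class AlleleBarcode:
    allele: str
    barcode_dna: str
    min_pairwise_hamming: int = 0


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_protein(protein: ProteinRecord, k: int, step: int = 1,
                 variant_tag: str = "WT") -> list[PeptideRecord]:
    """All length-``k`` windows of ``protein`` at the given residue step.

    The default step of one residue corresponds to a 3-bp in-frame shift
    between neighbouring tiles at the DNA level.  Returns L-k+1 windows
    (step 1) ordered by window start.
    """
    length = len(protein)
    if k > length:
        raise DesignError(
            f"window length {k} exceeds protein {protein.id!r} length {length}"
        )
    return [
        PeptideRecord(
            peptide=protein.sequence[start - 1:start - 1 + k],
            source_gene=protein.id,
            window_start=start,
            variant_tag=variant_tag,
        )
        for start in range(1, length - k + 2, step)
    ]


def windows_covering_position(protein: ProteinRecord, k: int, position: int,
                              variant_tag: str = "WT") -> list[PeptideRecord]:
    """Every length-``k`` window of ``protein`` that contains ``position``.

    An interior position (at least k-1 residues from both termini) is covered
    by exactly ``k`` windows; positions near a terminus by fewer.
    """
    length = len(protein)
    if not 1 <= position <= length:
        raise DesignError(
            f"position {position} out of range 1..{length} for {protein.id!r}"
        )
    first = max(1, position - k + 1)
    last = min(position, length - k + 1)
    return [
        PeptideRecord(
            peptide=protein.sequence[start - 1:start - 1 + k],
            source_gene=protein.id,
            window_start=start,
            variant_tag=variant_tag,
        )
        for start in range(first, last + 1)
    ]


def apply_variant(protein: ProteinRecord, variant: VariantSpec,
                  partner: ProteinRecord | None = None) -> ProteinRecord:
    """Apply a point substitution, in-frame deletion or fusion to a protein.

    For fusions the result concatenates residues 1..breakpoint_left of
    ``protein`` with residues breakpoint_right..end of ``partner``.
    """
    seq = protein.sequence
    if variant.kind == "point":
        pos = variant.position
        if not 1 <= pos <= len(seq):
            raise DesignError(f"{variant.tag}: position outside {protein.id!r}")
        if seq[pos - 1] != variant.ref_aa:
            raise DesignError(
                f"{variant.tag}: reference mismatch at position {pos} "
                f"(protein has {seq[pos - 1]!r}, variant expects {variant.ref_aa!r})"
            )
        new = seq[:pos - 1] + variant.alt_aa + seq[pos:]
        return ProteinRecord(id=f"{protein.id}|{variant.tag}", sequence=new)
    if variant.kind == "inframe_del":
        pos, dlen = variant.position, variant.del_length
        if not 1 <= pos <= len(seq) - dlen + 1:
            raise DesignError(f"{variant.tag}: deletion outside {protein.id!r}")
        new = seq[:pos - 1] + seq[pos - 1 + dlen:]
        return ProteinRecord(id=f"{protein.id}|{variant.tag}", sequence=new)
    if variant.kind == "fusion":
        if partner is None:
            raise DesignError(f"{variant.tag}: fusion requires a partner protein")
        bl, br = variant.breakpoint_left, variant.breakpoint_right
        if not 1 <= bl <= len(seq):
            raise DesignError(f"{variant.tag}: left breakpoint outside {protein.id!r}")
        if not 1 <= br <= len(partner.sequence):
            raise DesignError(f"{variant.tag}: right breakpoint outside {partner.id!r}")
        new = seq[:bl] + partner.sequence[br - 1:]
        return ProteinRecord(id=f"{protein.id}|{variant.tag}", sequence=new)
    raise DesignError(f"unknown variant kind {variant.kind!r}")


def junction_windows(fused: ProteinRecord, junction_index: int, k: int,
                     mode: str = "span",
                     variant_tag: str = "fusion") -> list[PeptideRecord]:
    """Windows of a fused protein laid across the junction.

    ``junction_index`` is the 1-based index of the last residue contributed by
    the left-hand fragment.  In ``"span"`` mode a window qualifies when it
    contains at least one residue from each side (k-1 windows for an interior
    junction).  In ``"position"`` mode the first right-side residue is treated
    like a mutated position and every window containing it is returned
    (k windows for an interior junction).
    """
    length = len(fused)
    if not 1 <= junction_index < length:
        raise DesignError(
            f"junction index {junction_index} not strictly interior to "
            f"{fused.id!r} (length {length})"
        )
    if mode == "span":
        first = max(1, junction_index - k + 2)
        last = min(junction_index, length - k + 1)
        starts = range(first, last + 1)
    elif mode == "position":
        return windows_covering_position(fused, k, junction_index + 1,
                                         variant_tag=variant_tag)
    else:
        raise DesignError(f"unknown junction mode {mode!r}")
    return [
        PeptideRecord(
            peptide=fused.sequence[s - 1:s - 1 + k],
            source_gene=fused.id,
            window_start=s,
            variant_tag=variant_tag,
        )
        for s in starts
    ]


def variant_windows(
    proteins: Mapping[str, ProteinRecord],
    variant: VariantSpec,
    ks: Sequence[int] = (9,),
    junction_mode: str = "span",
    include_wt: bool = True,
) -> tuple[list[PeptideRecord], list[tuple[str, str]]]:
    """Mutation-centred windows for one variant, optionally with WT counterparts.

    Returns the peptide records plus a (mut_peptide, wt_peptide) pairing list
    aligning each mutant window with the same-start window of the wild-type
    protein (point mutations only; junction windows have no WT counterpart by
    construction).
    """
    protein = proteins[variant.gene_id]
    records: list[PeptideRecord] = []
    pairs: list[tuple[str, str]] = []
    if variant.kind == "point":
        mutant = apply_variant(protein, variant)
        for k in ks:
            mut_windows = windows_covering_position(
                mutant, k, variant.position, variant_tag=variant.tag)
            records.extend(mut_windows)
            if include_wt:
                for w in mut_windows:
                    wt_pep = protein.sequence[w.window_start - 1:
                                              w.window_start - 1 + k]
                    records.append(PeptideRecord(
                        peptide=wt_pep, source_gene=protein.id,
                        window_start=w.window_start, variant_tag="WT"))
                    pairs.append((w.peptide, wt_pep))
    elif variant.kind == "inframe_del":
        mutant = apply_variant(protein, variant)
        junction = variant.position - 1
        for k in ks:
            if junction == 0:  # N-terminal deletion: cover the new first residue
                records.extend(windows_covering_position(
                    mutant, k, 1, variant_tag=variant.tag))
            else:
                records.extend(junction_windows(
                    mutant, junction, k, mode=junction_mode,
                    variant_tag=variant.tag))
    elif variant.kind == "fusion":
        partner = proteins[variant.partner_gene_id]
        fused = apply_variant(protein, variant, partner=partner)
        for k in ks:
            records.extend(junction_windows(
                fused, variant.breakpoint_left, k, mode=junction_mode,
                variant_tag=variant.tag))
    else:
        raise DesignError(f"unknown variant kind {variant.kind!r}")
    return records, pairs


# ---------------------------------------------------------------------------
# oligo encoding
# ---------------------------------------------------------------------------

def encode_oligo(peptide: str,
                 codon_table: Mapping[str, str] | None = None,
                 flank5: str = "", flank3: str = "",
                 forbidden_sites: Sequence[str] = DEFAULT_FORBIDDEN_SITES,
                 ) -> str:
    """Reverse-translate a peptide with a deterministic codon choice.

    Uses the most-used human codon per residue by default so a given library
    always encodes to the same oligos.  If the greedy encoding (including
    anchor junctions) contains a forbidden restriction site, each codon in
    turn is swapped for a synonymous alternative until the site disappears;
    an unavoidable site raises :class:`DesignError`.
    """
    table = dict(codon_table) if codon_table is not None else HUMAN_PREFERRED_CODON
    missing = set(peptide) - set(table)
    if missing:
        raise DesignError(f"codon table lacks residues {sorted(missing)}")
    codons = [table[aa] for aa in peptide]

    def assemble(cs: list[str]) -> str:
        return flank5 + "".join(cs) + flank3

    def has_site(s: str) -> bool:
        return any(site in s for site in forbidden_sites)

    oligo = assemble(codons)
    if not has_site(oligo):
        return oligo
    synonyms = synonymous_codons()
    for i, aa in enumerate(peptide):
        for alt in synonyms[aa]:
            trial = codons.copy()
            trial[i] = alt
            candidate = assemble(trial)
            if not has_site(candidate):
                return candidate
    raise DesignError(
        f"unavoidable forbidden site in encoding of {peptide!r}"
    )


def translate_oligo(oligo: str, flank5: str = "", flank3: str = "") -> str:
    """Translate the insert of an oligo (frame 0) after stripping flanks."""
    insert = oligo[len(flank5):len(oligo) - len(flank3) if flank3 else None]
    return str(Seq(insert).translate())


def encode_library(records: Iterable[PeptideRecord], flank5: str, flank3: str,
                   **kwargs) -> list[PeptideRecord]:
    """Attach oligos and anchors to every record (anchors must be >= 6 nt)."""
    if len(flank5) < 6 or len(flank3) < 6:
        raise DesignError("cloning anchors must be at least 6 nt")
    out = []
    for rec in records:
        oligo = encode_oligo(rec.peptide, flank5="", flank3="", **kwargs)
        out.append(replace(rec, oligo=oligo, flank5=flank5, flank3=flank3))
    return out


# ---------------------------------------------------------------------------
# allele barcodes
# ---------------------------------------------------------------------------

def synonymous_codons(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    """Residue -> synonymous codon tuple from an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in out.items()}


def barcode_capacity(tail_aa: str = B2M_TAIL_AA) -> int:
    """Number of distinct synonymous DNA encodings of the tail."""
    syn = synonymous_codons()
    cap = 1
    for aa in tail_aa:
        cap *= len(syn[aa])
    return cap


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def design_barcodes(alleles: Sequence[str] | int,
                    b2m_tail_aa: str = B2M_TAIL_AA,
                    min_hamming: int = 2,
                    seed: int = 0,
                    max_tries: int = 50_000) -> list[AlleleBarcode]:
    """Synonymous-codon barcodes on the invariant B2M tail, one per allele.

    Candidates are drawn in a seeded random order over the synonymous-codon
    space and accepted greedily when at Hamming distance >= ``min_hamming``
    from every barcode already accepted.  All barcodes translate back to the
    tail.  Raises :class:`BarcodeCapacityError` when the synonymous space is
    too small (or effectively exhausted) for the request.
    """
    if len(b2m_tail_aa) != 12:
        raise DesignError("B2M tail must be exactly 12 residues")
    if isinstance(alleles, int):
        alleles = [f"allele{i + 1:02d}" for i in range(alleles)]
    n = len(alleles)
    capacity = barcode_capacity(b2m_tail_aa)
    if capacity < n:
        raise BarcodeCapacityError(
            f"synonymous space of size {capacity} cannot hold {n} barcodes"
        )
    syn = synonymous_codons()
    choices = [syn[aa] for aa in b2m_tail_aa]
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    tries = 0
    while len(accepted) < n and tries < max_tries:
        tries += 1
        cand = "".join(cs[rng.integers(len(cs))] for cs in choices)
        if all(hamming(cand, prev) >= min_hamming for prev in accepted):
            accepted.append(cand)
    if len(accepted) < n:
        raise BarcodeCapacityError(
            f"could not place {n} barcodes at Hamming >= {min_hamming} in "
            f"{max_tries} draws (space size {capacity})"
        )
    for bc in accepted:
        if str(Seq(bc).translate()) != b2m_tail_aa:
            raise AssertionError("barcode does not translate to B2M tail")
    return [
        AlleleBarcode(allele=a, barcode_dna=bc, min_pairwise_hamming=min_hamming)
        for a, bc in zip(alleles, accepted)
    ]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_proteins_fasta(path) -> dict[str, ProteinRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
    return records


VARIANT_COLUMNS = ["gene", "kind", "position", "ref", "alt", "del_length",
                   "partner", "bp_left", "bp_right"]


def read_variant_table(path) -> list[VariantSpec]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        def _get(col, cast=None):
            v = row.get(col)
            if pd.isna(v):
                return None
            return cast(v) if cast else v
        out.append(VariantSpec(
            gene_id=row["gene"], kind=row["kind"],
            position=_get("position", int), ref_aa=_get("ref"),
            alt_aa=_get("alt"), del_length=_get("del_length", int),
            partner_gene_id=_get("partner"),
            breakpoint_left=_get("bp_left", int),
            breakpoint_right=_get("bp_right", int),
        ))
    return out


def library_to_frame(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "gene": [r.source_gene for r in records],
            "window_start": [r.window_start for r in records],
            "length": [r.length for r in records],
            "variant_tag": [r.variant_tag for r in records],
            "oligo": [r.oligo for r in records],
        }
    )


def write_library_tsv(records: Sequence[PeptideRecord], path) -> None:
    library_to_frame(records).to_csv(path, sep="\t", index=False)


def write_oligos_fasta(records: Sequence[PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f">{r.source_gene}|{r.variant_tag}|{r.window_start}|{i}\n")
            fh.write(f"{r.flank5}{r.oligo}{r.flank3}\n")


def write_barcode_tsv(barcodes: Sequence[AlleleBarcode], path) -> None:
    pd.DataFrame(
        {"allele": [b.allele for b in barcodes],
         "barcode_dna": [b.barcode_dna for b in barcodes]}
    ).to_csv(path, sep="\t", index=False)


def read_barcode_tsv(path) -> list[AlleleBarcode]:
    df = pd.read_csv(path, sep="\t")
    return [AlleleBarcode(allele=a, barcode_dna=b)
            for a, b in zip(df["allele"], df["barcode_dna"])]
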