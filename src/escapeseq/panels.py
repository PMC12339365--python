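"""HLA allele panels and shared construct constants.

The 50-allele combinatorial panel (14 HLA-A, 29 HLA-B, 7 HLA-C) covers the
most frequent class I alleles across world populations plus several
disease-associated alleles.  The 30-allele sub-panel is the one used for
mass-spectrometry cross-validation designs.
"""

from __future__ import annotations

HLA_A_PANEL: tuple[str, ...] = (
    "A*01:01", "A*02:01", "A*02:05", "A*02:12", "A*03:01", "A*11:01",
    "A*23:01", "A*24:02", "A*30:01", "A*31:01", "A*31:08", "A*34:01",
    "A*33:03", "A*68:01",
)

HLA_B_PANEL: tuple[str, ...] = (
    "B*07:02", "B*08:01", "B*08:02", "B*13:01", "B*15:01", "B*15:02",
    "B*15:03", "B*18:01", "B*27:01", "B*27:05", "B*27:02", "B*35:01",
    "B*35:02", "B*35:08", "B*39:06", "B*40:01", "B*40:06", "B*40:10",
    "B*41:01", "B*44:02", "B*46:01", "B*48:03", "B*50:01", "B*51:01",
    "B*52:01", "B*54:01", "B*56:01", "B*57:01", "B*58:01",
)

HLA_C_PANEL: tuple[str, ...] = (
    "C*03:04", "C*04:01", "C*06:02", "C*07:01", "C*07:02", "C*08:02",
    "C*12:03",
)

#: Full 50-allele combinatorial screening panel.
COMBINATORIAL_PANEL: tuple[str, ...] = HLA_A_PANEL + HLA_B_PANEL + HLA_C_PANEL

#: 30-allele sub-panel for MS-elution cross-validation designs
#: (first alleles of each locus, proportioned 10 A / 15 B / 5 C).
MS_VALIDATION_PANEL: tuple[str, ...] = (
    HLA_A_PANEL[:10] + HLA_B_PANEL[:15] + HLA_C_PANEL[:5]
)

#: The invariant 12-residue C-terminal tail of mature human beta-2
#: microglobulin, re-encoded with synonymous codons to barcode alleles.
B2M_TAIL_AA: str = "SQPKIVKWDRDM"


def locus_of(allele: str) -> str:
    """Return the HLA locus letter ('A', 'B' or 'C') of an allele name."""
    return allele.split("*", 1)[0][-1]
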