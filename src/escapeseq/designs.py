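"""Study-scale pool designs assembled from the library-design primitives.

Two combinatorial designs mirror the screens the toolkit targets:

* an oncogene pool of 92 recurrent point mutations and 31 fusion junctions,
  tiled with nine-mers (mutant plus wild-type counterpart windows, strict
  junction spanning) and 100 spike-in control peptides, crossed with the
  50-allele panel;
* an MS-validation pool of 986 peptides crossed with a 30-allele sub-panel.

Source proteins here are synthetic (seeded random sequences): the designs
exercise the pool arithmetic and provenance tracking, not any particular
oncogene's sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import libdesign as ld
from .panels import COMBINATORIAL_PANEL, MS_VALIDATION_PANEL
from .simdata import random_peptides

N_POINT_MUTATIONS = 92
N_FUSIONS = 31
N_SPIKEINS = 100
N_MS_PEPTIDES = 986


def _random_protein(rng: np.random.Generator, length: int, pid: str
                    ) -> ld.ProteinRecord:
    seq = "".join(rng.choice(list(ld.AA_ALPHABET), size=length))
    return ld.ProteinRecord(pid, seq)


def synthetic_oncogene_design(k: int = 9, seed: int = 0) -> pd.DataFrame:
    """Oncogene-pool peptides crossed with the 50-allele panel.

    Returns the peptide x allele pair table with provenance columns
    (peptide, variant_tag, allele).  Each point mutation contributes the k
    mutant windows covering an interior mutated residue plus their
    wild-type counterparts; each fusion contributes the k-1 strict-spanning
    junction windows; spike-in controls are standalone peptides.
    """
    rng = np.random.default_rng(seed)
    records: list[ld.PeptideRecord] = []
    proteins: dict[str, ld.ProteinRecord] = {}
    for i in range(N_POINT_MUTATIONS):
        gene = f"onco{i:03d}"
        prot = _random_protein(rng, 2 * k + 9, gene)
        proteins[gene] = prot
        pos = k + 2  # interior: full window complement on both sides
        ref = prot.sequence[pos - 1]
        alt = rng.choice([a for a in ld.AA_ALPHABET if a != ref])
        var = ld.VariantSpec(gene, "point", position=pos, ref_aa=ref,
                             alt_aa=str(alt))
        recs, _ = ld.variant_windows(proteins, var, ks=(k,), include_wt=True)
        records.extend(recs)
    for i in range(N_FUSIONS):
        left = _random_protein(rng, 2 * k, f"fusL{i:03d}")
        right = _random_protein(rng, 2 * k, f"fusR{i:03d}")
        proteins.update({left.id: left, right.id: right})
        var = ld.VariantSpec(left.id, "fusion", partner_gene_id=right.id,
                             breakpoint_left=k + 1, breakpoint_right=k)
        recs, _ = ld.variant_windows(proteins, var, ks=(k,),
                                     junction_mode="span")
        records.extend(recs)
    spike = random_peptides(N_SPIKEINS, k, rng)
    records.extend(
        ld.PeptideRecord(peptide=p, source_gene="spikein", window_start=1,
                         variant_tag="spikein")
        for p in spike)
    lib = ld.library_to_frame(records).drop_duplicates(subset="peptide")
    pairs = lib.merge(pd.DataFrame({"allele": COMBINATORIAL_PANEL}),
                      how="cross")
    return pairs


def synthetic_ms_design(k: int = 9, seed: int = 0) -> pd.DataFrame:
    """MS-validation pool: 986 peptides crossed with the 30-allele sub-panel."""
    rng = np.random.default_rng(seed)
    peptides = random_peptides(N_MS_PEPTIDES, k, rng)
    lib = pd.DataFrame({"peptide": peptides})
    return lib.merge(pd.DataFrame({"allele": MS_VALIDATION_PANEL}),
                     how="cross")
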