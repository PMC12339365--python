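"""Generative model of a pooled sort-seq presentation screen.

Emulates the full measurement chain with known ground truth: each construct
(peptide x allele single-chain trimer) has a latent presentation strength
theta in [0, 1] that sets its mean log-fluorescence between the background
peak (centre 100 a.u.) and the brightest signal (centre 6,400 a.u.).  Cells
receive log-normal fluorescence noise and are gated into four bins laid out
evenly on a log scale (gate boundaries at the geometric midpoints 200, 800
and 3,200 of the bin centres 100 / 400 / 1,600 / 6,400).  Sequencing reads
are drawn multinomially per bin in proportion to cell counts, and each read
is emitted as a FASTQ record carrying the peptide oligo and the allele
barcode between fixed anchors.  With probability ``recombination_rate`` a
read's barcode is swapped to a uniformly chosen other allele of the panel,
mimicking chimera formation during library PCR.

The model emulates: bimodal log-scale fluorescence, uneven construct
representation, finite sequencing depth and barcode recombination.  It does
not emulate base-call errors beyond optional anchor corruption (the
exact-match pipeline turns any base error into a categorized discard),
cell-cycle or expression heterogeneity beyond the log-normal noise term, or
per-experiment gate drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .libdesign import (AlleleBarcode, PeptideRecord, design_barcodes,
                        encode_library)
from .readproc import BINS, AnchorSpec, SpikeInDesign

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SorterModel:
    """Generative parameters of the simulated sorter and sequencer."""
    bin_centers: tuple = (100.0, 400.0, 1600.0, 6400.0)
    sigma_log10: float = 0.12          # log-normal fluorescence noise (log10 units)
    cells_per_construct: int = 1500    # library representation per replicate
    reads_per_bin: int | None = None   # default: 100 x number of constructs
    recombination_rate: float = 0.0    # barcode-swap probability per read
    anchor_corruption_rate: float = 0.0
    binder_fraction: float = 0.10      # mixture weight of the presenting mode
    theta_binder_range: tuple = (0.55, 1.0)
    theta_nonbinder_range: tuple = (0.0, 0.35)
    link: str = "linear"               # theta -> mean log-fluorescence link
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bin_centers) != 4 or np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("need 4 strictly increasing bin centers")
        if not 0 <= self.recombination_rate <= 1:
            raise ValueError("recombination_rate must lie in [0, 1]")

    @property
    def gates_log10(self) -> np.ndarray:
        """Gate boundaries: geometric midpoints of adjacent bin centres."""
        c = np.asarray(self.bin_centers)
        return np.log10(np.sqrt(c[:-1] * c[1:]))

    def mean_log10(self, theta: np.ndarray) -> np.ndarray:
        lo = np.log10(self.bin_centers[0])
        hi = np.log10(self.bin_centers[-1])
        theta = np.asarray(theta, dtype=float)
        if self.link == "linear":
            return lo + theta * (hi - lo)
        if self.link == "logistic":
            z = 1.0 / (1.0 + np.exp(-8.0 * (theta - 0.5)))
            z0 = 1.0 / (1.0 + np.exp(4.0))
            z1 = 1.0 / (1.0 + np.exp(-4.0))
            return lo + (z - z0) / (z1 - z0) * (hi - lo)
        raise ValueError(f"unknown link {self.link!r}")

    def bin_probabilities(self, theta: np.ndarray) -> np.ndarray:
        """P(cell of strength theta falls in each bin); rows sum to 1."""
        mean = self.mean_log10(theta)[:, None]
        if self.sigma_log10 == 0:
            edges = np.concatenate([[-np.inf], self.gates_log10, [np.inf]])
            out = np.zeros((mean.shape[0], 4))
            idx = np.searchsorted(edges, mean[:, 0], side="right") - 1
            out[np.arange(mean.shape[0]), idx] = 1.0
            return out
        cdf = stats.norm.cdf(self.gates_log10[None, :], loc=mean,
                             scale=self.sigma_log10)
        probs = np.diff(np.concatenate(
            [np.zeros_like(mean), cdf, np.ones_like(mean)], axis=1), axis=1)
        return probs

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class GroundTruth:
    """Latent state of a simulated screen."""
    constructs: pd.DataFrame        # peptide, allele, oligo, barcode, theta, label
    observed_counts: pd.DataFrame   # peptide, allele, bin, replicate, count (post-swap)
    latent_counts: pd.DataFrame     # same shape, pre-swap (true construct)
    n_chimeric: dict                # (bin, rep) -> swapped read count
    model: SorterModel


def truth_count_table(truth: GroundTruth) -> pd.DataFrame:
    """The count table implied by the emitted reads (oracle for demultiplexing).

    Demultiplexing the generated FASTQ with exact matching must reproduce
    this table bit-for-bit whenever anchor corruption is zero; chimeric reads
    are included because they still carry a valid (swapped) barcode.
    """
    return truth.observed_counts.copy()


@dataclass
class SimResult:
    fastq_files: dict               # (bin, replicate) -> path
    truth: GroundTruth
    anchors: AnchorSpec


def random_peptides(n: int, k: int, rng: np.random.Generator) -> list[str]:
    """Distinct random k-mer peptides."""
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(rng.choice(list(AA20), size=k)))
    return sorted(out)


def random_library(n: int, k: int, seed: int,
                   anchors: AnchorSpec | None = None) -> list[PeptideRecord]:
    anchors = anchors or AnchorSpec()
    rng = np.random.default_rng(seed)
    peps = random_peptides(n, k, rng)
    recs = [PeptideRecord(peptide=p, source_gene=f"synth{i:04d}",
                          window_start=1) for i, p in enumerate(peps)]
    return encode_library(recs, anchors.peptide_flank5, anchors.peptide_flank3)


def draw_thetas(n: int, model: SorterModel, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Latent presentation strengths from the binder/non-binder mixture."""
    labels = rng.random(n) < model.binder_fraction
    lo_b, hi_b = model.theta_binder_range
    lo_n, hi_n = model.theta_nonbinder_range
    theta = np.where(labels, rng.uniform(lo_b, hi_b, size=n),
                     rng.uniform(lo_n, hi_n, size=n))
    return theta, labels


def _corrupt_anchor(read: str, anchors: AnchorSpec,
                    rng: np.random.Generator) -> str:
    """Substitute one base inside the 5' peptide anchor."""
    pos = int(rng.integers(len(anchors.peptide_flank5)))
    old = read[pos]
    new = rng.choice([b for b in "ACGT" if b != old])
    return read[:pos] + new + read[pos + 1:]


def simulate_screen(
    library: Sequence[PeptideRecord],
    barcodes: Sequence[AlleleBarcode],
    model: SorterModel,
    replicates: int = 2,
    out_dir=None,
    constructs: pd.DataFrame | None = None,
    theta: np.ndarray | None = None,
    anchors: AnchorSpec | None = None,
    gzip_out: bool = False,
) -> SimResult:
    """Run the generative model and write FASTQ files per (bin, replicate).

    ``constructs`` restricts the screen to explicit (peptide, allele) pairs;
    by default the full library x panel cross is screened (combinatorial
    pooling).  ``theta`` overrides the mixture draw with explicit strengths,
    one per construct.  Everything is driven by ``model.seed``.
    """
    anchors = anchors or AnchorSpec()
    out_dir = Path(out_dir) if out_dir is not None else Path(".")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed)

    pep_info = {r.peptide: r for r in library}
    bc_info = {b.allele: b for b in barcodes}
    if constructs is None:
        constructs = pd.DataFrame(
            [(p, a) for p in pep_info for a in bc_info],
            columns=["peptide", "allele"])
    constructs = constructs.reset_index(drop=True)
    n = len(constructs)
    if n == 0:
        raise ValueError("no constructs to simulate")
    reads_per_bin = model.reads_per_bin or 100 * n
    if reads_per_bin <= 0:
        raise ValueError("zero-depth simulation requested")

    if theta is None:
        theta, labels = draw_thetas(n, model, rng)
    else:
        theta = np.asarray(theta, dtype=float)
        labels = theta >= model.theta_binder_range[0]

    truth_constructs = constructs.assign(
        oligo=[pep_info[p].oligo for p in constructs["peptide"]],
        barcode=[bc_info[a].barcode_dna for a in constructs["allele"]],
        theta=theta, label=labels)

    probs = model.bin_probabilities(theta)  # n x 4
    allele_names = list(bc_info)
    allele_idx = {a: i for i, a in enumerate(allele_names)}
    construct_allele = constructs["allele"].map(allele_idx).to_numpy()
    barcode_by_allele = [bc_info[a].barcode_dna for a in allele_names]

    fastq_files: dict = {}
    latent_rows = []
    observed_rows = []
    n_chimeric: dict = {}
    for rep_i in range(replicates):
        rep = f"R{rep_i + 1}"
        # cells sorted into bins, per construct
        cells = np.vstack([
            rng.multinomial(model.cells_per_construct, probs[i])
            for i in range(n)])  # n x 4
        for b_i, bin_name in enumerate(BINS):
            total_cells = cells[:, b_i].sum()
            if total_cells == 0:
                read_counts = np.zeros(n, dtype=int)
            else:
                read_counts = rng.multinomial(
                    reads_per_bin, cells[:, b_i] / total_cells)
            # reads in construct order; chimeras swap the barcode only
            construct_of_read = np.repeat(np.arange(n), read_counts)
            rng.shuffle(construct_of_read)
            n_reads = construct_of_read.size
            swap = rng.random(n_reads) < model.recombination_rate
            read_allele = construct_allele[construct_of_read].copy()
            if swap.any() and len(allele_names) > 1:
                offsets = rng.integers(1, len(allele_names), size=swap.sum())
                read_allele[swap] = (read_allele[swap] + offsets) % len(allele_names)
            n_chimeric[(bin_name, rep)] = int(swap.sum())

            # latent (true construct) and observed (post-swap) count tables
            lat = np.bincount(construct_of_read, minlength=n)
            for i in np.nonzero(lat)[0]:
                latent_rows.append((constructs.at[i, "peptide"],
                                    constructs.at[i, "allele"],
                                    bin_name, rep, int(lat[i])))
            obs_key = construct_of_read * len(allele_names) + read_allele
            obs = np.bincount(obs_key, minlength=n * len(allele_names))
            for key in np.nonzero(obs)[0]:
                ci, ai = divmod(key, len(allele_names))
                observed_rows.append((constructs.at[ci, "peptide"],
                                      allele_names[ai], bin_name, rep,
                                      int(obs[key])))

            path = out_dir / f"{bin_name}_{rep}.fastq"
            if gzip_out:
                path = path.with_suffix(".fastq.gz")
            corrupt = rng.random(n_reads) < model.anchor_corruption_rate
            _write_fastq(path, construct_of_read, read_allele, corrupt,
                         truth_constructs, barcode_by_allele, anchors,
                         bin_name, rep, rng)
            fastq_files[(bin_name, rep)] = path

    cols = ["peptide", "allele", "bin", "replicate", "count"]
    truth = GroundTruth(
        constructs=truth_constructs,
        observed_counts=_full_grid(pd.DataFrame(observed_rows, columns=cols),
                                   constructs["peptide"].unique(),
                                   allele_names, replicates),
        latent_counts=_full_grid(pd.DataFrame(latent_rows, columns=cols),
                                 constructs["peptide"].unique(),
                                 allele_names, replicates),
        n_chimeric=n_chimeric,
        model=model,
    )
    return SimResult(fastq_files=fastq_files, truth=truth, anchors=anchors)


def _full_grid(df: pd.DataFrame, peptides, alleles, replicates) -> pd.DataFrame:
    """Zero-fill the count table over the full grid, matching demux output."""
    reps = [f"R{i + 1}" for i in range(replicates)]
    idx = pd.MultiIndex.from_product(
        [sorted(peptides), list(alleles), list(BINS), reps],
        names=["peptide", "allele", "bin", "replicate"])
    # swapped barcodes can land several constructs on one cell: aggregate first
    agg = df.groupby(["peptide", "allele", "bin", "replicate"])["count"].sum()
    full = agg.reindex(idx, fill_value=0).reset_index()
    return full


def _write_fastq(path, construct_of_read, read_allele, corrupt,
                 constructs: pd.DataFrame, barcode_by_allele, anchors,
                 bin_name, rep, rng) -> None:
    oligos = constructs["oligo"].to_numpy()
    import gzip as _gzip
    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        chunks = []
        for r, (ci, ai) in enumerate(zip(construct_of_read, read_allele)):
            seq = (anchors.peptide_flank5 + oligos[ci] + anchors.peptide_flank3
                   + anchors.barcode_flank5 + barcode_by_allele[ai]
                   + anchors.barcode_flank3)
            if corrupt[r]:
                seq = _corrupt_anchor(seq, anchors, rng)
            chunks.append(f"@{bin_name}_{rep}_{r}\n{seq}\n+\n{'I' * len(seq)}\n")
            if len(chunks) >= 10_000:
                fh.write("".join(chunks))
                chunks = []
        fh.write("".join(chunks))


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

FIXTURE_SCALES = {"tiny": (20, 3), "small": (200, 10)}


def make_fixture(scale: str = "tiny", seed: int = 0,
                 **model_overrides) -> dict:
    """Bundled synthetic dataset: library, barcode panel and sorter model.

    ``tiny`` is 20 peptides x 3 alleles (fast, deterministic; used in unit
    tests and docs), ``small`` is 200 peptides x 10 alleles (parameter-
    recovery scale).
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown fixture scale {scale!r}")
    n_pep, n_alleles = FIXTURE_SCALES[scale]
    anchors = AnchorSpec()
    library = random_library(n_pep, k=9, seed=seed, anchors=anchors)
    barcodes = design_barcodes(n_alleles, min_hamming=2, seed=seed)
    model = SorterModel(seed=seed, **model_overrides)
    return {"library": library, "barcodes": barcodes, "model": model,
            "anchors": anchors}


def make_spikein_screen(n_pools: int = 2, alleles_per_pool: int = 5,
                        peptides_per_pool: int = 25, seed: int = 0,
                        **model_overrides) -> dict:
    """A screen of disjoint spike-in pools for chimera-rate estimation.

    Pool i pairs its own peptides only with its own alleles; any cross-pool
    read observed downstream evidences barcode recombination.
    """
    anchors = AnchorSpec()
    n_pep = n_pools * peptides_per_pool
    n_alleles = n_pools * alleles_per_pool
    library = random_library(n_pep, k=9, seed=seed, anchors=anchors)
    barcodes = design_barcodes(n_alleles, min_hamming=2, seed=seed)
    pools = {}
    pairs = []
    for i in range(n_pools):
        peps = [r.peptide for r in
                library[i * peptides_per_pool:(i + 1) * peptides_per_pool]]
        alls = [b.allele for b in
                barcodes[i * alleles_per_pool:(i + 1) * alleles_per_pool]]
        pools[f"pool{i + 1}"] = (frozenset(alls), frozenset(peps))
        pairs.extend((p, a) for p in peps for a in alls)
    design = SpikeInDesign(pools=pools)
    constructs = pd.DataFrame(pairs, columns=["peptide", "allele"])
    model = SorterModel(seed=seed, **model_overrides)
    return {"library": library, "barcodes": barcodes, "model": model,
            "anchors": anchors, "spikein": design, "constructs": constructs}
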