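"""Population-level coverage of presented mutations.

A diploid individual carries two alleles at each of HLA-A, -B and -C.  Given
the set of alleles that present at least one peptide of a mutation, and
population allele frequencies per locus, the coverage of that mutation is
the probability that a random individual carries at least one presenting
allele.  Under Hardy-Weinberg independence within and between loci this has
the closed form

    coverage = 1 - prod_locus (1 - p_locus)^2,

where p_locus is the summed frequency of presenting alleles at that locus.
Residual frequency mass not in the panel is treated as never presenting
(conservative).  A seeded Monte-Carlo sampler of diploid genotypes is
provided alongside the closed form as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LOCI = ("A", "B", "C")


class CoverageError(ValueError):
    pass


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies; each locus must sum to <= 1."""
    frequencies: pd.DataFrame  # columns: locus, allele, frequency

    def __post_init__(self) -> None:
        df = self.frequencies
        required = {"locus", "allele", "frequency"}
        if not required.issubset(df.columns):
            raise CoverageError(f"frequency table needs columns {sorted(required)}")
        if df.empty:
            raise CoverageError("empty allele frequency table")
        if (df["frequency"] < 0).any() or (df["frequency"] > 1).any():
            raise CoverageError("frequencies must lie in [0, 1]")
        sums = df.groupby("locus")["frequency"].sum()
        if (sums > 1 + 1e-9).any():
            raise CoverageError("per-locus frequencies must sum to <= 1")

    @classmethod
    def from_tsv(cls, path) -> "AlleleFrequencyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def locus_mass(self, alleles: Iterable[str]) -> dict[str, float]:
        """Summed frequency of the given alleles at each locus."""
        alleles = set(alleles)
        df = self.frequencies
        mass = {locus: 0.0 for locus in LOCI}
        sub = df[df["allele"].isin(alleles)]
        for locus, s in sub.groupby("locus")["frequency"].sum().items():
            mass[str(locus)] = float(s)
        return mass


@dataclass
class CoverageResult:
    mutation_id: str
    coverage: float
    mc_stderr: float
    presenting_alleles: frozenset
    analytic: float


def analytic_coverage(presenting: Iterable[str],
                      freqs: AlleleFrequencyTable) -> float:
    """Closed-form HWE coverage: 1 - prod_locus (1 - p_locus)^2."""
    mass = freqs.locus_mass(presenting)
    miss = 1.0
    for locus in LOCI:
        miss *= (1.0 - mass[locus]) ** 2
    return 1.0 - miss


def sample_coverage(presenting: Iterable[str], freqs: AlleleFrequencyTable,
                    n_individuals: int = 100_000, seed: int = 0,
                    mutation_id: str = "") -> CoverageResult:
    """Monte-Carlo coverage by sampling diploid genotypes.

    Each individual draws two alleles per locus independently from the
    frequency table (residual mass = non-panel, never presenting) and is
    covered when any of the six alleles presents.
    """
    presenting = set(presenting)
    unknown = presenting - set(freqs.frequencies["allele"])
    if unknown:
        raise CoverageError(
            f"presenting alleles absent from frequency table: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mass = freqs.locus_mass(presenting)
    covered = np.zeros(n_individuals, dtype=bool)
    for locus in LOCI:
        p = mass[locus]
        if p <= 0:
            continue
        # two HWE draws per locus; a draw "hits" when it lands in the
        # presenting-frequency mass
        draws = rng.random((n_individuals, 2))
        covered |= (draws < p).any(axis=1)
    cov = float(covered.mean())
    se = float(np.sqrt(cov * (1.0 - cov) / n_individuals))
    return CoverageResult(mutation_id=mutation_id, coverage=cov, mc_stderr=se,
                          presenting_alleles=frozenset(presenting),
                          analytic=analytic_coverage(presenting, freqs))


def presenting_alleles_by_mutation(calls: pd.DataFrame,
                                   mutation_of: Mapping[str, str]
                                   ) -> dict[str, set[str]]:
    """Alleles presenting >= 1 peptide of each mutation, from binder calls."""
    tagged = calls.assign(mutation=calls["peptide"].map(mutation_of))
    tagged = tagged.dropna(subset=["mutation"])
    out: dict[str, set[str]] = {m: set() for m in set(mutation_of.values())}
    pos = tagged[tagged["call"].astype(bool)]
    for mutation, sub in pos.groupby("mutation"):
        out[str(mutation)] = set(sub["allele"])
    return out


def coverage_distribution(calls: pd.DataFrame,
                          freqs: AlleleFrequencyTable,
                          mutation_of: Mapping[str, str],
                          n_individuals: int = 100_000,
                          seed: int = 0) -> pd.DataFrame:
    """Per-mutation population coverage table plus summary columns.

    Mutations with no tiling peptides in the call table get NaN coverage.
    The summary of interest downstream is the fraction of mutations with
    coverage above a chosen level (e.g. presented in at least one allele of
    a sampled individual).
    """
    presenting = presenting_alleles_by_mutation(calls, mutation_of)
    peptide_mutations = set(pd.Series(list(mutation_of.values())).unique())
    rows = []
    rng = np.random.default_rng(seed)
    for mutation in sorted(presenting):
        if mutation not in peptide_mutations:
            rows.append({"mutation": mutation, "coverage": np.nan,
                         "analytic": np.nan, "n_presenting_alleles": 0})
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = sample_coverage(presenting[mutation], freqs,
                              n_individuals=n_individuals, seed=sub_seed,
                              mutation_id=mutation)
        rows.append({"mutation": mutation, "coverage": res.coverage,
                     "analytic": res.analytic, "mc_stderr": res.mc_stderr,
                     "n_presenting_alleles": len(presenting[mutation])})
    return pd.DataFrame(rows)
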