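"""Bin-weighted enrichment scores (E-scores) for sort-seq presentation screens.

A construct ("trimer": one peptide fused to B2M and one HLA heavy chain) is
sorted into four fluorescence bins -- background, low, medium, high -- whose
centres sit at even log-scale spacing.  The E-score condenses the four read
counts of a trimer into one number:

1. depth normalization: each bin's counts are divided by that bin's mean
   count across trimers (no log transform);
2. per-trimer normalization: the four depth-normalized counts are divided by
   their sum, giving bin fractions that sum to one;
3. weighted sum with weights (0, 2, 4, 8) for (bg, low, med, high), weights
   laid out on the same log scale as the sort gates.

A raw E-score therefore lives in [0, 8]: 0 when all reads sit in the
background bin, 8 when all sit in the high bin.  In combinatorial screens the
E-score distribution of each allele is bimodal with a dominant negative peak;
per-allele additive shifts align those negative-peak modes across the panel
so that a single binder cutoff is meaningful (default cutoffs: 3.2 for a
single-allele screen, 3.8 for combinatorial screens; comparisons are strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .libdesign import AA_ALPHABET
from .readproc import BINS, BinCountTable

SINGLE_THRESHOLD = 3.2
COMBINATORIAL_THRESHOLD = 3.8
THRESHOLD_GUIDANCE_BAND = (3.5, 4.0)


@dataclass(frozen=True)
class EScoreWeights:
    """Bin weights; strictly increasing from background to high."""
    w_bg: float = 0.0
    w_low: float = 2.0
    w_med: float = 4.0
    w_high: float = 8.0

    def __post_init__(self) -> None:
        w = self.as_array()
        if not np.all(np.diff(w) > 0):
            raise ValueError("bin weights must increase strictly from bg to high")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_bg, self.w_low, self.w_med, self.w_high])


DEFAULT_WEIGHTS = EScoreWeights()


# ---------------------------------------------------------------------------
# normalization and scoring
# ---------------------------------------------------------------------------

def normalize_bins(counts: BinCountTable | pd.DataFrame) -> pd.DataFrame:
    """Two-step normalization of the raw count table.

    Step 1 divides each (bin, replicate) file's counts by the mean count
    across trimers in that file (sequencing-depth correction, no log).
    Step 2 divides each trimer's four-vector by its sum, yielding bin
    fractions summing to 1.  Trimers with zero reads in every bin are
    returned as NaN with ``missing=True``, never as zeros.

    Returns a frame indexed by (peptide, allele, replicate) with columns
    bg/low/med/high plus a boolean ``missing`` column.
    """
    df = counts.counts if isinstance(counts, BinCountTable) else counts
    wide = df.pivot_table(index=["peptide", "allele", "replicate"],
                          columns="bin", values="count", fill_value=0)
    for b in BINS:
        if b not in wide.columns:
            wide[b] = 0
    wide = wide[list(BINS)].astype(float)
    # per-(bin, replicate) depth normalization
    rep_level = wide.index.get_level_values("replicate")
    for rep in pd.unique(rep_level):
        mask = rep_level == rep
        means = wide.loc[mask].mean(axis=0)
        means = means.replace(0, np.nan)  # empty bin file: leave zeros as zeros
        wide.loc[mask] = wide.loc[mask].div(means.fillna(1.0), axis=1)
    totals = wide.sum(axis=1)
    missing = totals == 0
    fractions = wide.div(totals.where(~missing), axis=0)
    fractions["missing"] = missing
    return fractions


def compute_escore(fractions: pd.DataFrame | np.ndarray,
                   weights: EScoreWeights = DEFAULT_WEIGHTS) -> pd.Series | np.ndarray:
    """Weighted sum of bin fractions; bounded in [0, w_high]."""
    w = weights.as_array()
    if isinstance(fractions, pd.DataFrame):
        return fractions[list(BINS)].to_numpy() @ w
    return np.asarray(fractions) @ w


def escore_table(counts: BinCountTable | pd.DataFrame,
                 weights: EScoreWeights = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Raw E-scores per (peptide, allele, replicate) from a count table."""
    fr = normalize_bins(counts)
    out = fr.index.to_frame(index=False)
    out["escore"] = compute_escore(fr, weights)
    out.loc[fr["missing"].to_numpy(), "escore"] = np.nan
    return out


# ---------------------------------------------------------------------------
# per-allele mode alignment
# ---------------------------------------------------------------------------

def _lower_mode(scores: np.ndarray, valley: float, bw_method: str,
                grid_size: int) -> float | None:
    """Highest-density point of the negative (lower) E-score peak.

    Gaussian KDE on scores below the valley threshold; the mode is the argmax
    on a fixed grid, so alignment is reproducible to grid resolution.
    """
    low = scores[scores < valley]
    if low.size < 2 or np.ptp(low) == 0:
        return None
    kde = stats.gaussian_kde(low, bw_method=bw_method)
    grid = np.linspace(low.min(), min(valley, low.max()), grid_size)
    return float(grid[np.argmax(kde(grid))])


def align_alleles(scores: pd.DataFrame,
                  valley: float = 4.0,
                  bw_method: str = "silverman",
                  min_trimers: int = 50,
                  grid_size: int = 512) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift each allele's E-scores so negative-peak modes coincide.

    Operates per (allele, replicate).  The reference is the median of the
    estimated modes within each replicate; shifts are additive.  Alleles with
    fewer than ``min_trimers`` scored trimers, or without a resolvable lower
    peak, are left unshifted with a warning.

    Returns (scores with an ``aligned`` column, shift table with columns
    allele, replicate, mode, shift).
    """
    scores = scores.copy()
    rows = []
    for rep, rep_df in scores.groupby("replicate", sort=False):
        modes = {}
        for allele, sub in rep_df.groupby("allele", sort=False):
            vals = sub["escore"].dropna().to_numpy()
            if vals.size < min_trimers:
                warnings.warn(
                    f"allele {allele} (rep {rep}): only {vals.size} trimers; "
                    "no mode alignment applied")
                modes[allele] = None
                continue
            modes[allele] = _lower_mode(vals, valley, bw_method, grid_size)
            if modes[allele] is None:
                warnings.warn(
                    f"allele {allele} (rep {rep}): lower peak not resolvable; "
                    "no shift applied")
        found = [m for m in modes.values() if m is not None]
        reference = float(np.median(found)) if found else 0.0
        for allele, mode in modes.items():
            shift = 0.0 if mode is None else reference - mode
            rows.append({"replicate": rep, "allele": allele,
                         "mode": np.nan if mode is None else mode,
                         "shift": shift})
    shifts = pd.DataFrame(rows)
    key = shifts.set_index(["replicate", "allele"])["shift"]
    scores["aligned"] = scores["escore"] + key.reindex(
        pd.MultiIndex.from_frame(scores[["replicate", "allele"]])
    ).to_numpy()
    return scores, shifts


# ---------------------------------------------------------------------------
# binder calls, QC and summaries
# ---------------------------------------------------------------------------

def default_threshold(mode: str) -> float:
    if mode == "single":
        return SINGLE_THRESHOLD
    if mode == "combinatorial":
        return COMBINATORIAL_THRESHOLD
    raise ValueError(f"unknown screening mode {mode!r}")


def call_binders(scores: pd.Series | np.ndarray, mode: str = "combinatorial",
                 threshold: float | None = None):
    """Strict-inequality binder calls (score > threshold).

    Default cutoffs are 3.2 (single-allele) and 3.8 (combinatorial); an
    override outside the 3.5-4.0 guidance band triggers a warning but is
    honoured.
    """
    if threshold is None:
        threshold = default_threshold(mode)
    else:
        lo, hi = THRESHOLD_GUIDANCE_BAND
        if not lo <= threshold <= hi:
            warnings.warn(
                f"binder threshold {threshold} outside guidance band [{lo}, {hi}]")
    return scores > threshold


def replicate_qc(scores: pd.DataFrame, value: str = "escore",
                 min_r: float = 0.9) -> pd.DataFrame:
    """Pairwise Pearson correlation between replicates, per allele.

    Fails an allele when r <= ``min_r`` or when r is undefined (constant
    replicate vector).
    """
    rows = []
    for allele, sub in scores.groupby("allele", sort=False):
        wide = sub.pivot_table(index="peptide", columns="replicate",
                               values=value)
        reps = list(wide.columns)
        if len(reps) < 2:
            raise ValueError(f"allele {allele}: replicate QC needs >= 2 replicates")
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                paired = wide[[reps[i], reps[j]]].dropna()
                x, y = paired[reps[i]], paired[reps[j]]
                if x.nunique() <= 1 or y.nunique() <= 1:
                    rows.append({"allele": allele, "rep_a": reps[i],
                                 "rep_b": reps[j], "pearson_r": np.nan,
                                 "pass": False, "note": "constant vector"})
                    continue
                r = float(stats.pearsonr(x, y).statistic)
                rows.append({"allele": allele, "rep_a": reps[i],
                             "rep_b": reps[j], "pearson_r": r,
                             "pass": r > min_r, "note": ""})
    return pd.DataFrame(rows)


def aggregate_replicates(scores: pd.DataFrame, value: str = "aligned"
                         ) -> pd.DataFrame:
    """Mean score across replicates per (peptide, allele)."""
    col = value if value in scores.columns else "escore"
    return (scores.groupby(["peptide", "allele"], sort=False)[col]
            .mean().rename("escore").reset_index())


def build_motif(peptides: Sequence[str], pseudocount: float = 0.0
                ) -> pd.DataFrame:
    """Position-frequency matrix (k x 20) of a positive peptide set.

    Rows are 1-based positions, columns the 20 canonical residues; each row
    sums to one (with optional pseudocount smoothing).
    """
    if not peptides:
        raise ValueError("cannot build a motif from an empty peptide set")
    k = len(peptides[0])
    if any(len(p) != k for p in peptides):
        raise ValueError("motif construction requires equal-length peptides")
    counts = np.full((k, len(AA_ALPHABET)), pseudocount, dtype=float)
    col = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for p in peptides:
        for i, aa in enumerate(p):
            counts[i, col[aa]] += 1
    pfm = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(pfm, index=pd.RangeIndex(1, k + 1, name="position"),
                        columns=list(AA_ALPHABET))


def capture_percentage(ms_detected: Iterable[tuple[str, str]],
                       binders: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Fraction of MS-detected (peptide, allele) pairs called by the screen.

    Reported per allele; an allele with an empty MS set is flagged NaN.
    """
    ms = set(ms_detected)
    pos = set(binders)
    if not ms:
        raise ValueError("empty MS reference set; capture percentage undefined")
    alleles = sorted({a for _, a in ms})
    rows = []
    for allele in alleles:
        ms_a = {p for p, a in ms if a == allele}
        hit = len({p for p in ms_a if (p, allele) in pos})
        rows.append({"allele": allele, "n_ms": len(ms_a), "n_captured": hit,
                     "capture": hit / len(ms_a)})
    return pd.DataFrame(rows)


QUADRANTS = ("WT-Mut-", "WT+Mut+", "WT+only", "Mut+only")


def quadrant_classify(pairs: pd.DataFrame,
                      threshold: float = COMBINATORIAL_THRESHOLD
                      ) -> pd.DataFrame:
    """Classify mutant/wild-type E-score pairs into four presentation groups.

    ``pairs`` needs columns ``mut_escore`` and ``wt_escore`` (plus any id
    columns, carried through).  Strict comparisons against the threshold on
    both axes produce WT-Mut-, WT+Mut+, WT+only and Mut+only classes; rows
    with a missing score are excluded with a warning.
    """
    out = pairs.copy()
    usable = out[["mut_escore", "wt_escore"]].notna().all(axis=1)
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} unpaired/missing rows excluded "
                      "from quadrant classification")
        out = out[usable].copy()
    mut_pos = out["mut_escore"] > threshold
    wt_pos = out["wt_escore"] > threshold
    cls = np.select(
        [~wt_pos & ~mut_pos, wt_pos & mut_pos, wt_pos & ~mut_pos],
        [QUADRANTS[0], QUADRANTS[1], QUADRANTS[2]], default=QUADRANTS[3])
    out["quadrant"] = cls
    return out


def quadrant_percentages(classified: pd.DataFrame,
                         by: str | None = "allele") -> pd.DataFrame:
    keys = [by] if by and by in classified.columns else []
    grp = classified.groupby(keys + ["quadrant"]).size().rename("n").reset_index()
    totals = grp.groupby(keys)["n"].transform("sum") if keys else grp["n"].sum()
    grp["percent"] = 100.0 * grp["n"] / totals
    return grp


def sharing_profile(calls: pd.DataFrame,
                    mutation_of: Mapping[str, str] | None = None
                    ) -> tuple[pd.Series, pd.DataFrame | None]:
    """How broadly peptides are shared across alleles.

    Returns the per-peptide count of presenting alleles (including zeros) and,
    when a peptide -> mutation map is given, the per (mutation, allele) count
    of presented tiling peptides.
    """
    per_peptide = (calls.groupby("peptide")["call"].sum().astype(int)
                   .rename("n_alleles"))
    per_mutation = None
    if mutation_of is not None:
        tagged = calls.assign(mutation=calls["peptide"].map(mutation_of))
        tagged = tagged.dropna(subset=["mutation"])
        per_mutation = (tagged.groupby(["mutation", "allele"])["call"]
                        .sum().astype(int).rename("n_presented").reset_index())
    return per_peptide, per_mutation


# ---------------------------------------------------------------------------
# convenience: full scoring pipeline
# ---------------------------------------------------------------------------

def score_screen(counts: BinCountTable | pd.DataFrame,
                 mode: str = "combinatorial",
                 align: bool = True,
                 threshold: float | None = None,
                 weights: EScoreWeights = DEFAULT_WEIGHTS,
                 min_trimers: int = 50,
                 ) -> dict:
    """Count table -> per-replicate E-scores, alignment, mean scores, calls.

    Alignment (when enabled and in combinatorial mode) happens per replicate;
    replicate scores are then averaged and binder calls are made on the mean.
    Returns a dict with keys ``scores`` (per replicate), ``shifts``, ``mean``
    (peptide, allele, escore, call) and ``threshold``.
    """
    per_rep = escore_table(counts, weights=weights)
    shifts = None
    if align:
        per_rep, shifts = align_alleles(per_rep, min_trimers=min_trimers)
        mean = aggregate_replicates(per_rep, value="aligned")
    else:
        mean = aggregate_replicates(per_rep, value="escore")
    thr = threshold if threshold is not None else default_threshold(mode)
    mean["call"] = call_binders(mean["escore"], mode=mode, threshold=thr) \
        if threshold is not None else mean["escore"] > thr
    return {"scores": per_rep, "shifts": shifts, "mean": mean,
            "threshold": thr}
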