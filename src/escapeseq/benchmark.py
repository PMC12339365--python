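"""Benchmarking E-scores against affinity and elution references.

Regression metrics (Pearson/Spearman) against log-transformed IC50 and
classification metrics (ROC-AUC, PR-AUC) against the conventional 500 nM
binder threshold, computed separately per allele with nonparametric
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

IC50_BINDER_NM = 500.0
IC50_SCALE_NM = 50_000.0
RANK_STRONG = 0.5
RANK_WEAK = 2.0


def transform_affinity(ic50_nm):
    """Map IC50 (nM) to the conventional 0-1 affinity scale.

    t = 1 - log(ic50) / log(50000): 1 at 1 nM, 0 at 50,000 nM, monotone
    decreasing; 500 nM maps to 0.426.  The log base cancels in the ratio.
    """
    ic50 = np.asarray(ic50_nm, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("IC50 must be positive (nM)")
    out = 1.0 - np.log10(ic50) / np.log10(IC50_SCALE_NM)
    return float(out) if np.isscalar(ic50_nm) else out


def inverse_transform_affinity(t):
    """Inverse of :func:`transform_affinity` (returns IC50 in nM)."""
    t = np.asarray(t, dtype=float)
    out = IC50_SCALE_NM ** (1.0 - t)
    return float(out) if out.ndim == 0 else out


def label_binders(reference: pd.DataFrame) -> pd.Series:
    """Binary binder labels from an affinity/elution reference table.

    IC50 strictly below 500 nM is positive; where IC50 is absent the elution
    flag passes through.  Rows with neither label raise.
    """
    has_ic50 = "ic50_nm" in reference.columns
    has_eluted = "eluted" in reference.columns
    if not has_ic50 and not has_eluted:
        raise ValueError("reference needs an ic50_nm or eluted column")
    labels = pd.Series(pd.NA, index=reference.index, dtype="boolean")
    if has_ic50:
        ic50 = reference["ic50_nm"]
        labels[ic50.notna()] = ic50[ic50.notna()] < IC50_BINDER_NM
    if has_eluted:
        el = reference["eluted"]
        fill = labels.isna() & el.notna()
        labels[fill] = el[fill].astype(bool)
    if labels.isna().any():
        raise ValueError(f"{int(labels.isna().sum())} rows carry no usable label")
    return labels.astype(bool)


@dataclass
class MetricReport:
    n: int
    n_positive: int
    pearson_r: float = np.nan
    spearman_r: float = np.nan
    roc_auc: float = np.nan
    pr_auc: float = np.nan
    ci: dict = field(default_factory=dict)   # metric -> (low, high)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_positive": self.n_positive,
             "pearson_r": self.pearson_r, "spearman_r": self.spearman_r,
             "roc_auc": self.roc_auc, "pr_auc": self.pr_auc}
        for m, (lo, hi) in self.ci.items():
            d[f"{m}_ci_low"], d[f"{m}_ci_high"] = lo, hi
        return d


def classification_metrics(scores, labels) -> dict:
    """ROC-AUC (Mann-Whitney concordance, ties half-credit) and PR-AUC.

    PR-AUC uses step-wise interpolation of the precision-recall staircase
    (average precision), avoiding the optimistic bias of trapezoids.
    Single-class input yields NaN metrics with a flag rather than an error.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        return {"roc_auc": np.nan, "pr_auc": np.nan, "flag": "single_class",
                "roc_curve": None, "pr_curve": None}
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr_auc": float(average_precision_score(labels, scores)),
        "flag": None,
        "roc_curve": (fpr, tpr),
        "pr_curve": (prec, rec),
    }


def regression_metrics(scores, targets) -> dict:
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.unique(scores).size <= 1 or np.unique(targets).size <= 1:
        return {"pearson_r": np.nan, "spearman_r": np.nan,
                "flag": "constant_input"}
    return {
        "pearson_r": float(stats.pearsonr(scores, targets).statistic),
        "spearman_r": float(stats.spearmanr(scores, targets).statistic),
        "flag": None,
    }


def bootstrap_ci(metric_fn: Callable[..., float], *arrays,
                 B: int = 1000, level: float = 0.95, seed: int = 0,
                 min_n: int = 20) -> tuple[float, float, int]:
    """Percentile bootstrap interval of a metric over paired arrays.

    Draws ``B`` resamples with replacement; resamples on which the metric is
    undefined (exception or NaN, e.g. a single-class ROC draw) are skipped
    and counted.  Returns (low, high, n_skipped).
    """
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    if n < min_n:
        raise ValueError(f"bootstrap needs at least {min_n} observations, got {n}")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            v = metric_fn(*(a[idx] for a in arrays))
        except Exception:
            skipped += 1
            continue
        if v is None or (isinstance(v, float) and np.isnan(v)):
            skipped += 1
            continue
        vals.append(v)
    if not vals:
        raise ValueError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi), skipped


def evaluate(scores, reference: pd.DataFrame, B: int = 1000,
             seed: int = 0, bootstrap: bool = True) -> MetricReport:
    """Full per-allele metric report for one score/reference pairing."""
    scores = np.asarray(scores, dtype=float)
    labels = label_binders(reference).to_numpy()
    report = MetricReport(n=len(scores), n_positive=int(labels.sum()))
    cls = classification_metrics(scores, labels)
    report.roc_auc, report.pr_auc = cls["roc_auc"], cls["pr_auc"]
    if cls["flag"]:
        report.flags.append(cls["flag"])
    if "ic50_nm" in reference.columns and reference["ic50_nm"].notna().all():
        t = transform_affinity(reference["ic50_nm"].to_numpy())
        reg = regression_metrics(scores, t)
        report.pearson_r = reg["pearson_r"]
        report.spearman_r = reg["spearman_r"]
        if reg["flag"]:
            report.flags.append(reg["flag"])
    if bootstrap and not report.flags:
        t = (transform_affinity(reference["ic50_nm"].to_numpy())
             if "ic50_nm" in reference.columns
             and reference["ic50_nm"].notna().all() else None)
        def _roc(s, l):
            return roc_auc_score(l, s)
        report.ci["roc_auc"] = bootstrap_ci(_roc, scores, labels,
                                            B=B, seed=seed)[:2]
        if t is not None:
            def _pearson(s, tt):
                return stats.pearsonr(s, tt).statistic
            report.ci["pearson_r"] = bootstrap_ci(_pearson, scores, t,
                                                  B=B, seed=seed + 1)[:2]
    return report


def evaluate_per_allele(scored: pd.DataFrame, reference: pd.DataFrame,
                        score_col: str = "escore", B: int = 1000,
                        seed: int = 0, bootstrap: bool = False
                        ) -> pd.DataFrame:
    """Metrics separately for each allele; pooled row appended last."""
    merged = scored.merge(reference, on=["peptide", "allele"], how="inner")
    rows = []
    for allele, sub in merged.groupby("allele", sort=True):
        rep = evaluate(sub[score_col].to_numpy(), sub, B=B, seed=seed,
                       bootstrap=bootstrap)
        rows.append({"allele": allele, **rep.to_dict()})
    pooled = evaluate(merged[score_col].to_numpy(), merged, B=B, seed=seed,
                      bootstrap=bootstrap)
    rows.append({"allele": "__pooled__", **pooled.to_dict()})
    return pd.DataFrame(rows)


def recall_by_bin(calls, reference_positive, bins) -> pd.DataFrame:
    """Recall (called positive / reference positive) within each affinity bin.

    ``bins`` is an ordinal label per observation; empty bins report NaN.
    """
    df = pd.DataFrame({"call": np.asarray(calls, dtype=bool),
                       "positive": np.asarray(reference_positive, dtype=bool),
                       "bin": np.asarray(bins)})
    rows = []
    for b in pd.unique(df["bin"]):
        sub = df[(df["bin"] == b) & df["positive"]]
        rows.append({"bin": b, "n_positive": len(sub),
                     "recall": sub["call"].mean() if len(sub) else np.nan})
    return pd.DataFrame(rows)


def read_predictor_table(path) -> pd.DataFrame:
    """Harmonize an external predictor's TSV (peptide, allele, score, mode).

    Percentile-rank scores are additionally classified with the standard
    0.5% (strong) and 2% (weak) cutoffs.  Missing predictions stay missing
    rather than being treated as negatives.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"predictor table needs columns {sorted(required)}")
    if "mode" not in df.columns:
        df["mode"] = "score"
    is_rank = df["mode"].astype(str).str.contains("rank", case=False)
    df["binder_class"] = pd.NA
    rank = df.loc[is_rank, "score"]
    df.loc[is_rank, "binder_class"] = np.select(
        [rank < RANK_STRONG, rank < RANK_WEAK],
        ["strong", "weak"], default="non-binder")
    return df


def roc_auc_concordance(scores, labels) -> float:
    """All-pairs Mann-Whitney concordance oracle for ROC-AUC (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("concordance undefined with a single class")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (pos.size * neg.size))
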