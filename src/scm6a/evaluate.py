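"""Evaluation protocol: R², tolerance labels, pooled AUROC, balanced
accuracy, permutation nulls, correlations, metagene profiles.

The regression metric is R².  Binary accuracy labels follow the tolerance
rule: a prediction counts as correct when it lies within ``tolerance``
(default 0.5, inclusive) of the truth.  The ROC construction discriminates
the model's actual (truth, prediction) pairs from seeded random re-pairings
of the same values, scoring every pair by the negative absolute difference;
AUROC is the Mann–Whitney rank statistic on that pool, so an accurate model
scores near 1 while any permuted pairing collapses to 0.5.  Balanced accuracy
from scores is the maximum over ROC thresholds.  Metric distributions are
summarized by median and quartiles (they are generally non-normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .config import EvalConfig

__all__ = [
    "r_squared",
    "tolerance_labels",
    "rank_auroc",
    "AurocResult",
    "auroc_tolerance",
    "balanced_accuracy",
    "balanced_accuracy_from_scores",
    "permutation_null",
    "correlate",
    "metagene_profile",
    "EvalReport",
    "evaluate_predictions",
]


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SSE/SST."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 2:
        raise ValueError("need at least 2 pairs")
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero variance in y_true; R² undefined")
    sse = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - sse / sst


def tolerance_labels(y_true, y_pred, tolerance: float = 0.5) -> np.ndarray:
    """1 where |prediction - truth| <= tolerance (inclusive), else 0."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("vectors are misaligned")
    return (np.abs(y_pred - y_true) <= tolerance).astype(int)


def rank_auroc(labels, scores) -> float:
    """AUROC as the Mann–Whitney statistic U / (n1 * n0); ties count half."""
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


@dataclass
class AurocResult:
    """Pooled ROC of matched vs re-paired (truth, prediction) pairs."""

    auroc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    labels: np.ndarray
    scores: np.ndarray


def auroc_tolerance(y_true, y_pred, cfg: EvalConfig | None = None,
                    ) -> AurocResult:
    """ROC analysis of prediction fidelity via matched-vs-resampled pairs.

    The pool holds the n matched (truth, prediction) pairs as positives and n
    seeded random re-pairings (truth_i with prediction_sigma(i)) as the
    negative-enriched resample; every pair is scored by -|prediction - truth|.
    AUROC is the rank statistic of the scores against the pool labels: 1 when
    matched errors are uniformly smaller than mismatched ones, 0.5 when the
    pairing carries no information.
    """
    cfg = cfg or EvalConfig()
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("vectors are misaligned")
    rng = np.random.default_rng(cfg.seed)
    sigma = rng.permutation(y_true.size)
    scores = np.concatenate([-np.abs(y_pred - y_true),
                             -np.abs(y_pred[sigma] - y_true)])
    labels = np.concatenate([np.ones(y_true.size, int),
                             np.zeros(y_true.size, int)])
    auc = rank_auroc(labels, scores)
    fpr, tpr, thr = roc_curve(labels, scores)
    return AurocResult(auc, fpr, tpr, thr, labels, scores)


def balanced_accuracy(labels_true, labels_pred) -> float:
    """Mean of sensitivity and specificity."""
    labels_true = np.asarray(labels_true, int)
    labels_pred = np.asarray(labels_pred, int)
    if labels_true.min() == labels_true.max():
        raise ValueError("balanced accuracy undefined: single-class truth")
    pos = labels_true == 1
    sens = float((labels_pred[pos] == 1).mean())
    spec = float((labels_pred[~pos] == 0).mean())
    return (sens + spec) / 2.0


def balanced_accuracy_from_scores(labels, scores) -> float:
    """Best achievable balanced accuracy over all ROC thresholds."""
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise ValueError("balanced accuracy undefined: single-class labels")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, float))
    return float(((tpr + (1.0 - fpr)) / 2.0).max())


def permutation_null(metric, y_true, y_pred, cfg: EvalConfig | None = None):
    """Null distribution of a pairing-dependent metric under shuffling.

    ``metric(y_true, y_pred_permuted)`` is recomputed ``n_permutations``
    times with the prediction order shuffled (seeded).  Returns
    ``(observed, null_values, p)`` with the +1-corrected empirical p-value
    ``(1 + #{null >= observed}) / (1 + n_valid)``; permutations on which the
    metric is not computable are recorded as NaN and excluded from p.
    """
    cfg = cfg or EvalConfig()
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    rng = np.random.default_rng(cfg.seed)
    observed = metric(y_true, y_pred)
    null = np.full(cfg.n_permutations, np.nan)
    for i in range(cfg.n_permutations):
        perm = rng.permutation(y_pred.size)
        try:
            null[i] = metric(y_true, y_pred[perm])
        except (ValueError, ZeroDivisionError):
            pass
    valid = null[np.isfinite(null)]
    p = (1.0 + float((valid >= observed).sum())) / (1.0 + valid.size)
    return observed, null, p


def correlate(a, b, cfg: EvalConfig | None = None):
    """Correlation with pairwise deletion of missing values.

    Returns ``(R, P, n)`` using Pearson (two-sided t) or Spearman.
    """
    cfg = cfg or EvalConfig()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    if cfg.correlation_method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(a.size)


def metagene_profile(peaks: pd.DataFrame, annotation: pd.DataFrame,
                     bins_per_region: int = 10):
    """Density of peak midpoints over a standardized transcript model.

    Each peak's midpoint is assigned to the 5'UTR, CDS or 3'UTR of its
    transcript, rescaled to [0, 1) within that region and binned into
    ``bins_per_region`` bins per region (30 bins total by default, 5'UTR
    first).  Returns ``(profile, n_skipped)``: the profile sums to 1 when any
    peak maps; peaks on transcripts lacking region annotation are skipped and
    counted.

    ``peaks`` needs columns transcript_id (or chrom), start, end in
    transcript coordinates; ``annotation`` needs transcript_id and
    utr5_len/cds_len/utr3_len.
    """
    ann = annotation.set_index("transcript_id")
    tx_col = "transcript_id" if "transcript_id" in peaks.columns else "chrom"
    counts = np.zeros(3 * bins_per_region)
    skipped = 0
    for _, pk in peaks.iterrows():
        tx = pk[tx_col]
        if tx not in ann.index:
            skipped += 1
            continue
        u5, cds, u3 = (float(ann.at[tx, c]) for c in
                       ("utr5_len", "cds_len", "utr3_len"))
        mid = (float(pk["start"]) + float(pk["end"])) / 2.0
        total = u5 + cds + u3
        if not (0 <= mid < total):
            skipped += 1
            continue
        if mid < u5:
            region, frac = 0, mid / u5
        elif mid < u5 + cds:
            region, frac = 1, (mid - u5) / cds
        else:
            region, frac = 2, (mid - u5 - cds) / u3
        b = min(int(frac * bins_per_region), bins_per_region - 1)
        counts[region * bins_per_region + b] += 1
    total_mass = counts.sum()
    profile = counts / total_mass if total_mass > 0 else counts
    return profile, skipped


def _quartiles(values: list[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if np.isfinite(v)], float)
    if arr.size == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


@dataclass
class EvalReport:
    """Per-site metrics plus pooled median/quartile summaries."""

    per_site: pd.DataFrame
    summary: dict = field(default_factory=dict)
    nulls: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_site": {
                col: {site: (None if not np.isfinite(v) else round(float(v), 10))
                      for site, v in self.per_site[col].items()}
                for col in self.per_site.columns
            },
            "summary": self.summary,
            "nulls": {k: [round(float(v), 10) if np.isfinite(v) else None
                          for v in vals]
                      for k, vals in self.nulls.items()},
            "correlations": self.correlations,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_tsv(self, path: str | Path) -> None:
        self.per_site.to_csv(path, sep="\t", index_label="site")


def evaluate_predictions(y_true: pd.DataFrame, y_pred: pd.DataFrame,
                         cfg: EvalConfig | None = None) -> EvalReport:
    """Per-site R², AUROC and balanced accuracy for a sites x cells pair.

    Sites and cells are intersected and aligned.  Balanced accuracy is the
    max-threshold value on each site's matched-vs-resampled ROC pool;
    degenerate sites (zero truth variance, single-class pools) yield NaN.
    """
    cfg = cfg or EvalConfig()
    sites = [s for s in y_true.index if s in y_pred.index]
    cells = [c for c in y_true.columns if c in y_pred.columns]
    if not sites or not cells:
        raise ValueError("no overlapping sites/cells between truth and prediction")
    rows = []
    for s in sites:
        yt = y_true.loc[s, cells].to_numpy(float)
        yp = y_pred.loc[s, cells].to_numpy(float)
        ok = np.isfinite(yt) & np.isfinite(yp)
        yt, yp = yt[ok], yp[ok]
        try:
            r2 = r_squared(yt, yp)
        except ValueError:
            r2 = float("nan")
        try:
            roc = auroc_tolerance(yt, yp, cfg)
            auc = roc.auroc
            ba = balanced_accuracy_from_scores(roc.labels, roc.scores)
        except ValueError:
            auc, ba = float("nan"), float("nan")
        rows.append({"r2": r2, "auroc": auc, "balanced_accuracy": ba})
    per_site = pd.DataFrame(rows, index=sites)
    summary = {col: _quartiles(per_site[col].tolist())
               for col in per_site.columns}
    return EvalReport(per_site=per_site, summary=summary)
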