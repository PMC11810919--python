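"""Segmentation evaluation: seven per-case metrics and cohort aggregation.

Per case (one 2D slice), on masks binarized at a threshold:

* DSC  = 2TP / (2TP + FP + FN)        (Dice similarity coefficient)
* JSC  = TP / (TP + FP + FN)          (Jaccard)
* PPV  = TP / (TP + FP)               (positive predictive value)
* SE   = TP / (TP + FN)               (sensitivity)
* HD   — symmetric Hausdorff distance between foreground point sets,
  Euclidean, in pixel units (plain max-min; a 95th-percentile variant is
  available but off by default)
* RVD  = |(TP+FP) - (TP+FN)| / (TP+FN)  (relative volume difference,
  reported as absolute value; a signed variant is available)
* VOE  = 1 - JSC                      (volumetric overlap error)

Degenerate-case policy: an empty prediction against a non-empty truth scores
dsc=jsc=ppv=se=0, rvd=1, voe=1 and hd equal to the image diagonal; cases with
empty ground truth raise :class:`EmptyTruthError` and are excluded from
aggregation (counted in ``n_excluded``), which keeps cohort statistics
defined without discarding failures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

METRIC_NAMES = ("dsc", "jsc", "ppv", "se", "hd", "rvd", "voe")


class EmptyTruthError(ValueError):
    """Ground-truth mask contains no foreground."""


class EmptyMaskError(ValueError):
    """Hausdorff distance is undefined for an empty mask."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    dsc: float
    jsc: float
    ppv: float
    se: float
    hd: float
    rvd: float
    voe: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class MetricSummary:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    sd_defined: bool = True


@dataclass
class AggregateReport:
    stats: dict[str, MetricSummary]
    n_cases: int
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_excluded": self.n_excluded,
            "metrics": {k: asdict(v) for k, v in self.stats.items()},
        }


# ---------------------------------------------------------------------------
# per-case metrics
# ---------------------------------------------------------------------------


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities: pixel = 1 iff p >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    p = np.asarray(pred_mask).astype(bool)
    g = np.asarray(truth_mask).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(
    c: ConfusionCounts, signed_rvd: bool = False
) -> tuple[float, float, float, float, float, float]:
    """(dsc, jsc, ppv, se, rvd, voe) from pixel counts.

    Raises :class:`EmptyTruthError` when the ground truth is empty.
    """
    if c.tp + c.fn == 0:
        raise EmptyTruthError("ground truth has no foreground pixels")
    dsc = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    jsc = c.tp / (c.tp + c.fp + c.fn)
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else 0.0
    se = c.tp / (c.tp + c.fn)
    rvd = ((c.tp + c.fp) - (c.tp + c.fn)) / (c.tp + c.fn)
    if not signed_rvd:
        rvd = abs(rvd)
    voe = 1.0 - jsc
    return dsc, jsc, ppv, se, rvd, voe


def hausdorff(
    pred_mask: np.ndarray, truth_mask: np.ndarray, percentile: float | None = None
) -> float:
    """Symmetric Hausdorff distance between foreground point sets (Euclidean,
    pixel units).  ``percentile`` switches to the robust variant (e.g. 95)."""
    a = np.argwhere(np.asarray(pred_mask).astype(bool))
    b = np.argwhere(np.asarray(truth_mask).astype(bool))
    if len(a) == 0 or len(b) == 0:
        raise EmptyMaskError("Hausdorff distance requires two non-empty masks")
    if percentile is None:
        d_ab = directed_hausdorff(a, b)[0]
        d_ba = directed_hausdorff(b, a)[0]
        return float(max(d_ab, d_ba))
    from scipy.spatial import cKDTree

    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(
        max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
    )


def evaluate_case(
    pred: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    signed_rvd: bool = False,
    hd_percentile: float | None = None,
) -> MetricReport:
    """All seven metrics for one probability map against one binary truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pm = binarize(pred, threshold)
    c = confusion(pm, truth)
    if c.tp + c.fn == 0:
        raise EmptyTruthError("ground truth has no foreground pixels")
    dsc, jsc, ppv, se, rvd, voe = overlap_metrics(c, signed_rvd=signed_rvd)
    if pm.any():
        hd = hausdorff(pm, truth, percentile=hd_percentile)
    else:
        hd = math.hypot(truth.shape[0] - 1, truth.shape[1] - 1)  # image diagonal
        rvd = -1.0 if signed_rvd else 1.0
    return MetricReport(dsc, jsc, ppv, se, hd, rvd, voe)


def evaluate_cases(
    pairs, threshold: float = 0.5, **kw
) -> tuple[list[MetricReport], int]:
    """Evaluate an iterable of (pred, truth) pairs; empty-truth cases are
    skipped and counted."""
    reports, excluded = [], 0
    for pred, truth in pairs:
        try:
            reports.append(evaluate_case(pred, truth, threshold, **kw))
        except EmptyTruthError:
            excluded += 1
    return reports, excluded


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _summary(values: np.ndarray) -> MetricSummary:
    x = np.asarray(values, dtype=np.float64)
    mean = float(x.mean())
    sd_defined = len(x) > 1
    sd = float(x.std(ddof=1)) if sd_defined else 0.0
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    iqr = q3 - q1
    in_low = x[x >= q1 - 1.5 * iqr]
    in_high = x[x <= q3 + 1.5 * iqr]
    return MetricSummary(
        mean=mean,
        sd=sd,
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        sd_defined=sd_defined,
    )


def aggregate(reports: list[MetricReport], n_excluded: int = 0) -> AggregateReport:
    """Cohort statistics per metric: mean, sample sd (n-1), median, quartiles
    (linear interpolation), and 1.5*IQR whiskers clipped to observed data."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    stats = {
        name: _summary([getattr(r, name) for r in reports]) for name in METRIC_NAMES
    }
    return AggregateReport(stats=stats, n_cases=len(reports), n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def reports_to_csv(reports: list[MetricReport], path) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in reports])
    df.index.name = "case"
    df.to_csv(path)
    return df


def aggregate_to_json(agg: AggregateReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(agg.as_dict(), fh, indent=2)


def boxstats_to_csv(agg: AggregateReport, path) -> pd.DataFrame:
    """Box-plot statistics (median, quartiles, whiskers) as CSV for external
    plotting."""
    rows = []
    for name, s in agg.stats.items():
        rows.append(
            {
                "metric": name,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
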