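"""Segmentation metrics and the paired t-test for A/B comparisons.

Per-image metrics treat the lesion as the positive class:
accuracy = (TP+TN)/(TP+FP+FN+TN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), Dice = 2TP/(2TP+FP+FN).

The preprocessing experiment compares one metric across two runs over
the same images with a two-tailed paired Student t-test on the per-image
differences (sample SD, n-1 denominator), significant at p < 0.05.
95% confidence intervals are reported per arm (mean +/- t_{0.975,df} *
SE of that arm), mirroring the usual reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ShapeError

__all__ = ["SegmentationMetrics", "PairedTestResult", "compute_metrics", "paired_t_test"]

ALPHA = 0.05


@dataclass(frozen=True)
class SegmentationMetrics:
    """Confusion counts and derived fractions for one predicted mask.

    ``sensitivity_defined`` is False when the ground truth contains no
    lesion pixels (sensitivity is then reported as 0 by convention).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    dice: float
    sensitivity_defined: bool = True


@dataclass(frozen=True)
class PairedTestResult:
    """Two-tailed paired t-test summary for metric arms a and b.

    ``sd_diff``/``se_diff`` describe the per-image differences a - b;
    the confidence intervals are per arm.  ``degenerate`` flags the
    zero-variance case (all differences identical and nonzero).
    """

    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    se_a: float
    se_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    sd_diff: float
    se_diff: float
    t: float
    df: int
    p: float
    significant: bool
    degenerate: bool = False


def compute_metrics(pred: np.ndarray, gt: np.ndarray) -> SegmentationMetrics:
    """Confusion counts and metric fractions of ``pred`` against ``gt``."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ShapeError(
            f"prediction {pred.shape} and ground truth {gt.shape} shapes differ"
        )
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    total = tp + fp + fn + tn
    pos = tp + fn
    sens_defined = pos > 0
    return SegmentationMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / total,
        sensitivity=tp / pos if sens_defined else 0.0,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else 0.0,
        dice=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0,
        sensitivity_defined=sens_defined,
    )


def _arm_summary(values: np.ndarray, tcrit: float):
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    se = sd / np.sqrt(values.size)
    return mean, sd, se, (mean - tcrit * se, mean + tcrit * se)


def paired_t_test(metric_a, metric_b, alpha: float = ALPHA) -> PairedTestResult:
    """Two-tailed paired t-test of per-image metrics a vs b.

    ``t = mean(a - b) / (sd(a - b) / sqrt(n))`` with sample SD and
    ``df = n - 1``; p from the Student-t distribution.  Zero-variance
    differences give t = 0, p = 1 when the arms agree exactly, and a
    degenerate result (p = 0) when they differ by a common constant.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("metric arms must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    df = n - 1
    sd_d = float(d.std(ddof=1))
    se_d = sd_d / np.sqrt(n)
    degenerate = False
    if sd_d == 0.0:
        if d.mean() == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if d.mean() > 0 else -np.inf
            p = 0.0
            degenerate = True
    else:
        t = float(d.mean() / se_d)
        p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    mean_a, sd_a, se_a, ci_a = _arm_summary(a, tcrit)
    mean_b, sd_b, se_b, ci_b = _arm_summary(b, tcrit)
    return PairedTestResult(
        n=n,
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        se_a=se_a,
        se_b=se_b,
        ci_a=ci_a,
        ci_b=ci_b,
        sd_diff=sd_d,
        se_diff=float(se_d),
        t=t,
        df=df,
        p=p,
        significant=p < alpha,
        degenerate=degenerate,
    )
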