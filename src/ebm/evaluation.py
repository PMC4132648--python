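"""Diagnostics from stages: distributions by label and threshold classification.

Stage-threshold classification declares a subject positive (converter, or
case) when their stage is at least the threshold; sweeping the threshold
over 0..N+1 traces the ROC curve.  Balanced accuracy — the mean of
sensitivity and specificity — is prevalence-independent and is the criterion
used to pick the operating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import MetricError


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity (all in percent)."""
    return (sensitivity + specificity) / 2.0


def stage_distribution(stages, labels, n_stages: int) -> pd.DataFrame:
    """Per-stage proportion of subjects within each diagnostic label.

    Returns an (n_stages+1) x L table; each label column sums to 1.
    """
    stages = np.asarray(stages, dtype=int)
    labels = np.asarray(labels, dtype=object)
    if stages.shape != labels.shape:
        raise ValueError("stages and labels must be the same length")
    uniq = sorted(set(labels))
    out = pd.DataFrame(index=pd.RangeIndex(n_stages + 1, name="stage"), columns=uniq, dtype=float)
    for lab in uniq:
        counts = np.bincount(stages[labels == lab], minlength=n_stages + 1)
        out[lab] = counts / counts.sum()
    return out


@dataclass
class ClassificationReport:
    """Operating point at the balanced-accuracy-maximising stage threshold."""

    threshold_stage: int
    balanced_accuracy: float  # percent
    sensitivity: float        # percent
    specificity: float        # percent
    auc: float                # in [0, 1]
    n_positive: int
    n_negative: int


def classify_by_stage(stages, outcome):
    """Sweep stage thresholds and report the balanced-accuracy optimum.

    ``outcome`` is binary (0 = stable/control, 1 = converter/case); a subject
    is classified positive iff stage >= threshold.  Returns
    ``(ClassificationReport, sweep)`` where ``sweep`` is the full threshold
    table (threshold, sensitivity, specificity, balanced accuracy).  Ties in
    balanced accuracy resolve to the lowest threshold.  AUC is the
    Mann-Whitney rank statistic on stages (ties counted 1/2), identical to
    the trapezoid area under the swept ROC points.
    """
    stages = np.asarray(stages, dtype=int)
    outcome = np.asarray(outcome, dtype=int)
    if stages.shape != outcome.shape:
        raise ValueError("stages and outcome must be the same length")
    if not set(np.unique(outcome)) <= {0, 1}:
        raise MetricError("outcome must be binary 0/1")
    n_pos = int(outcome.sum())
    n_neg = int(len(outcome) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("both outcome classes must be present")

    n_max = int(stages.max())
    rows = []
    for t in range(0, n_max + 2):
        pred = stages >= t
        sens = 100.0 * np.mean(pred[outcome == 1])
        spec = 100.0 * np.mean(~pred[outcome == 0])
        rows.append(
            {
                "threshold": t,
                "sensitivity": sens,
                "specificity": spec,
                "balanced_accuracy": balanced_accuracy(sens, spec),
            }
        )
    sweep = pd.DataFrame(rows)
    best = int(sweep["balanced_accuracy"].idxmax())  # idxmax -> lowest threshold on ties

    ranks = rankdata(stages)
    auc = (ranks[outcome == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    report = ClassificationReport(
        threshold_stage=int(sweep.loc[best, "threshold"]),
        balanced_accuracy=float(sweep.loc[best, "balanced_accuracy"]),
        sensitivity=float(sweep.loc[best, "sensitivity"]),
        specificity=float(sweep.loc[best, "specificity"]),
        auc=float(auc),
        n_positive=n_pos,
        n_negative=n_neg,
    )
    return report, sweep


def roc_auc_trapezoid(sweep: pd.DataFrame) -> float:
    """Trapezoid AUC over the swept ROC points (cross-check for the rank AUC)."""
    # The sweep is ordered by ascending threshold, so fpr and tpr are jointly
    # non-increasing; reversing yields the ROC vertices in ascending order
    # with endpoints (0,0) and (1,1) included.
    fpr = (1.0 - sweep["specificity"].to_numpy() / 100.0)[::-1]
    tpr = (sweep["sensitivity"].to_numpy() / 100.0)[::-1]
    return float(np.trapezoid(tpr, fpr))
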