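"""Clinical-performance evaluation of the nodal-risk classifier.

Sensitivity and specificity are prevalence-free, but the predictive values a
clinician acts on are not: PPV and NPV are recomputed from sensitivity,
specificity and an assumed prevalence by Bayes' rule, so the same test can
be re-expressed for an unselected cystectomy population (23% nodal
involvement) or a higher-risk subset (39% among T3 tumors). Risk tiers are
summarised by relative risks against the complement of each tier, with 95%
confidence intervals by the Katz log-normal approximation; discrimination
by ROC AUC (the Mann-Whitney probability that a random node-positive
patient outscores a random node-negative one, ties counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from nodalrisk.predictor import RiskResult

__all__ = [
    "ConfusionSummary",
    "GroupRiskEstimate",
    "PerformanceReport",
    "confusion_metrics",
    "ppv_npv_at_prevalence",
    "relative_risk",
    "roc_auc",
    "evaluate",
]

RISK_CLASSES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        """tp / (tp + fn); NaN when no positives exist."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        """tn / (tn + fp); NaN when no negatives exist."""
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan


@dataclass(frozen=True)
class GroupRiskEstimate:
    """Relative risk of one risk tier versus its comparator.

    ``continuity_corrected`` flags estimates where 0.5 was added to every
    cell because an arm had zero events; ``defined`` is False when the
    group or its complement is empty.
    """

    group: str
    rr: float
    ci_low: float
    ci_high: float
    events_in: int
    n_in: int
    events_out: int
    n_out: int
    continuity_corrected: bool = False
    defined: bool = True


@dataclass(frozen=True)
class PerformanceReport:
    confusion: ConfusionSummary
    prevalence: float
    ppv: float
    npv: float
    auc: float
    group_risks: tuple[GroupRiskEstimate, ...]


def _as_binary(labels: Sequence[int], what: str = "labels") -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError(f"empty {what}")
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError(f"{what} must be binary 0/1")
    return arr.astype(int)


def confusion_metrics(
    risk_classes: Sequence[str],
    labels: Sequence[int],
    positive_classes: tuple[str, ...] = ("high",),
) -> ConfusionSummary:
    """Confusion counts treating the given risk tiers as test-positive.

    Default dichotomisation calls only the high-risk tier positive;
    intermediate and low count as test-negative (pass
    ``positive_classes=("high", "intermediate")`` to change that).
    """
    y = _as_binary(labels)
    classes = list(risk_classes)
    if len(classes) != len(y):
        raise ValueError("risk_classes and labels must have equal length")
    unknown = set(classes) - set(RISK_CLASSES)
    if unknown:
        raise ValueError(f"unknown risk class(es): {sorted(unknown)}")
    pred = np.array([c in positive_classes for c in classes])
    return ConfusionSummary(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def ppv_npv_at_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Predictive values at an assumed prevalence, by Bayes' rule.

    ppv = sens*prev / (sens*prev + (1-spec)*(1-prev))
    npv = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev)
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]; got {v}")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if ppv_den == 0 or npv_den == 0:
        raise ValueError("degenerate denominator: predictive value undefined")
    ppv = sensitivity * prevalence / ppv_den
    npv = specificity * (1 - prevalence) / npv_den
    return ppv, npv


def relative_risk(
    group_membership: Sequence[int] | Sequence[bool],
    labels: Sequence[int],
    group: str = "group",
    reference: Literal["complement", "cohort"] = "complement",
    z: float = 1.959963984540054,
) -> GroupRiskEstimate:
    """Risk ratio of in-group samples versus a comparator, with a 95% CI.

    With the default ``reference="complement"`` (the standard
    epidemiological choice), RR = (events_in / n_in) / (events_out /
    n_out); with ``reference="cohort"`` the comparator is the whole cohort.
    The CI uses the Katz log-normal approximation, exp(ln RR ± z *
    sqrt(1/a - 1/n_in + 1/c - 1/n_out)) with a, c the event counts in the
    two arms. If either arm has zero events, 0.5 is added to every cell and
    the result is flagged ``continuity_corrected``.
    """
    member = np.asarray(group_membership).astype(bool)
    y = _as_binary(labels)
    if len(member) != len(y):
        raise ValueError("group_membership and labels must have equal length")
    n_in = int(member.sum())
    if reference == "complement":
        n_out = int((~member).sum())
        c = int(y[~member].sum())
    elif reference == "cohort":
        n_out = len(y)
        c = int(y.sum())
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if n_in == 0 or n_out == 0:
        raise ValueError("need at least one sample inside and outside the group")
    a = int(y[member].sum())
    corrected = a == 0 or c == 0
    af, cf, nif, nof = (
        (a + 0.5, c + 0.5, n_in + 1.0, n_out + 1.0) if corrected
        else (float(a), float(c), float(n_in), float(n_out))
    )
    rr = (af / nif) / (cf / nof)
    se = math.sqrt(1 / af - 1 / nif + 1 / cf - 1 / nof)
    ci_low = rr * math.exp(-z * se)
    ci_high = rr * math.exp(z * se)
    return GroupRiskEstimate(
        group=group,
        rr=rr,
        ci_low=ci_low,
        ci_high=ci_high,
        events_in=a,
        n_in=n_in,
        events_out=c,
        n_out=n_out,
        continuity_corrected=corrected,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve of the posterior scores.

    Equals the Mann-Whitney probability P(score+ > score-) + 0.5 * P(tie)
    over all positive-negative pairs. Both outcome classes must be present.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to compute AUC")
    return float(roc_auc_score(y, s))


def evaluate(
    predictions: Sequence[RiskResult],
    labels: Sequence[int],
    prevalence_override: float | None = None,
    positive_classes: tuple[str, ...] = ("high",),
    rr_reference: Literal["complement", "cohort"] = "complement",
) -> PerformanceReport:
    """Full clinical-performance report for a set of risk predictions.

    Sensitivity, specificity, AUC and per-tier relative risks come from the
    cohort itself; PPV/NPV are recomputed at ``prevalence_override`` when
    given (e.g. 0.39 for a T3-restricted testing population), otherwise at
    the cohort's observed prevalence. Tiers absent from the predictions get
    an undefined (flagged) relative-risk entry.
    """
    y = _as_binary(labels)
    if len(predictions) != len(y):
        raise ValueError("predictions and labels must have equal length")
    classes = [r.risk_class for r in predictions]
    scores = [r.p for r in predictions]
    confusion = confusion_metrics(classes, y, positive_classes=positive_classes)
    prevalence = (
        prevalence_override if prevalence_override is not None else float(y.mean())
    )
    # degenerate dichotomizations (e.g. every sample in one tier) make one
    # predictive value undefined; report NaN there rather than failing
    sens, spec = confusion.sensitivity, confusion.specificity
    ppv_den = sens * prevalence + (1 - spec) * (1 - prevalence)
    npv_den = spec * (1 - prevalence) + (1 - sens) * prevalence
    ppv = sens * prevalence / ppv_den if ppv_den > 0 else math.nan
    npv = spec * (1 - prevalence) / npv_den if npv_den > 0 else math.nan
    auc = roc_auc(scores, y)
    groups = []
    for tier in RISK_CLASSES:
        member = np.array([c == tier for c in classes])
        if member.all() or not member.any():
            groups.append(
                GroupRiskEstimate(
                    group=tier, rr=math.nan, ci_low=math.nan, ci_high=math.nan,
                    events_in=int(y[member].sum()), n_in=int(member.sum()),
                    events_out=int(y[~member].sum()), n_out=int((~member).sum()),
                    defined=False,
                )
            )
        else:
            groups.append(relative_risk(member, y, group=tier, reference=rr_reference))
    return PerformanceReport(
        confusion=confusion,
        prevalence=prevalence,
        ppv=ppv,
        npv=npv,
        auc=auc,
        group_risks=tuple(groups),
    )
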