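"""Spearman-similarity Bayesian weighted nearest-neighbor nodal-risk predictor.

A query tumor's panel profile is compared with every profile in a labeled
reference cohort by Spearman rank correlation. Positively correlated
references vote for their nodal label with weight ``max(rho, 0)**gamma``,
and the vote is smoothed toward a baseline prevalence pi0 acting as a
Bayesian prior with pseudo-count mass ``s``:

    p = (s * pi0 + sum_i w_i * y_i) / (s + sum_i w_i)

so p is always a convex combination of pi0 and the reference labels and
lies in [0, 1]. With ``s = 0`` the score is a pure weighted vote; as
``s -> inf`` it collapses to the prior. Because only ranks of the query
profile enter, the score is invariant to any strictly increasing transform
of the query's expression values.

The resulting posterior risk is stratified against the baseline prevalence
of nodal involvement at cystectomy (23%) into three tiers:
high (p > 0.247), intermediate (0.227 <= p <= 0.247), low (p < 0.227).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nodalrisk.io import ExpressionMatrix, ReferenceCohort

__all__ = [
    "PredictorParams",
    "RiskThresholds",
    "RiskResult",
    "spearman_correlation",
    "posterior_risk",
    "classify_risk",
    "predict_cohort",
]

RiskClass = Literal["low", "intermediate", "high"]


@dataclass(frozen=True)
class PredictorParams:
    """Knobs of the weighted nearest-neighbor posterior.

    k : number of most-correlated reference samples used (0 = all).
        Ties with the k-th correlation are all retained.
    weight_exponent : exponent gamma applied to positive correlations.
    prior_strength : pseudo-count mass s placed on the baseline prior.
    baseline_prevalence : prior probability pi0 of nodal involvement
        (default 0.23, the prevalence at radical cystectomy).
    """

    k: int = 0
    weight_exponent: float = 1.0
    prior_strength: float = 1.0
    baseline_prevalence: float = 0.23

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.prior_strength < 0:
            raise ValueError("prior_strength must be >= 0")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")


@dataclass(frozen=True)
class RiskThresholds:
    """Risk-tier cutpoints on the posterior probability.

    Defaults are the clinically recommended cutoffs around the 23% baseline
    prevalence: low below 0.227, high above 0.247, intermediate on the
    closed interval between them.
    """

    t_low: float = 0.227
    t_high: float = 0.247

    def __post_init__(self) -> None:
        if not 0 < self.t_low <= self.t_high < 1:
            raise ValueError("require 0 < t_low <= t_high < 1")


@dataclass
class RiskResult:
    """Posterior risk for one query sample.

    ``prior_fallback`` flags the degenerate case where no reference sample
    received positive weight and no prior mass was configured, in which
    case p defaults to the baseline prevalence.
    """

    sample_id: str
    p: float
    risk_class: RiskClass | None = None
    prior_fallback: bool = False
    neighbor_detail: pd.DataFrame | None = field(default=None, repr=False)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Equals the Pearson correlation of the two rank vectors; for tie-free
    data it reduces to ``1 - 6*sum(d^2) / (n*(n^2-1))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks of each row, centered and L2-normalised.

    Rows with zero rank variance (constant profiles) are returned as zero
    vectors, so their correlation with anything is 0.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, ranks / np.where(norms == 0, 1.0, norms), 0.0)
    return out


def _neighbor_weights(
    rho: np.ndarray, params: PredictorParams
) -> np.ndarray:
    """Per-reference weights: top-k selection then max(rho, 0)**gamma."""
    keep = np.ones_like(rho, dtype=bool)
    if params.k > 0 and params.k < len(rho):
        kth = np.sort(rho)[::-1][params.k - 1]
        keep = rho >= kth  # ties with the k-th correlation all retained
    w = np.where(keep, np.clip(rho, 0.0, None), 0.0)
    with np.errstate(invalid="ignore"):
        w = np.power(w, params.weight_exponent, where=w > 0, out=np.zeros_like(w))
    # 0**0 -> a zero-correlation neighbor never votes, whatever gamma
    return w


def _posterior_from_correlations(
    rho: np.ndarray, y: np.ndarray, params: PredictorParams
) -> tuple[float, bool, np.ndarray]:
    """Prior-smoothed weighted label vote given per-reference correlations.

    Returns ``(p, prior_fallback, weights)`` with
    p = (s * pi0 + sum w_i y_i) / (s + sum w_i), falling back to pi0 when
    both the prior mass and every weight are zero.
    """
    w = _neighbor_weights(np.asarray(rho, float), params)
    s, pi0 = params.prior_strength, params.baseline_prevalence
    total = s + w.sum()
    if total == 0:
        return pi0, True, w
    return float((s * pi0 + w @ np.asarray(y, float)) / total), False, w


def posterior_risk(
    query: Sequence[float],
    cohort: ReferenceCohort,
    params: PredictorParams | None = None,
    keep_detail: bool = False,
) -> RiskResult:
    """Posterior probability of nodal involvement for one query profile.

    The query vector must align with the cohort's probe order. Returns a
    :class:`RiskResult` with ``p`` set and ``risk_class`` left to
    :func:`classify_risk`.
    """
    params = params or PredictorParams()
    q = np.asarray(query, float)
    if q.ndim != 1 or len(q) != cohort.matrix.n_probes:
        raise ValueError(
            f"query length {q.shape} does not match panel size {cohort.matrix.n_probes}"
        )
    if np.ptp(q) == 0:
        raise ValueError("constant query profile: rank correlation undefined")
    q_ranked = _rank_rows(q[None, :])[0]
    ref_ranked = _rank_rows(cohort.matrix.values.to_numpy(float))
    rho = ref_ranked @ q_ranked
    y = cohort.labels.to_numpy(float)
    p, fallback, w = _posterior_from_correlations(rho, y, params)
    detail = None
    if keep_detail:
        detail = pd.DataFrame(
            {"rho": rho, "weight": w, "label": cohort.labels.to_numpy()},
            index=cohort.matrix.sample_ids,
        )
    return RiskResult(sample_id="query", p=p, prior_fallback=fallback, neighbor_detail=detail)


def classify_risk(p: float, thresholds: RiskThresholds | None = None) -> RiskClass:
    """Map a posterior probability to a low/intermediate/high risk tier.

    The intermediate interval is closed: p equal to either cutpoint is
    intermediate.
    """
    thresholds = thresholds or RiskThresholds()
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1]; got {p}")
    if p > thresholds.t_high:
        return "high"
    if p < thresholds.t_low:
        return "low"
    return "intermediate"


def predict_cohort(
    queries: ExpressionMatrix,
    cohort: ReferenceCohort,
    params: PredictorParams | None = None,
    thresholds: RiskThresholds | None = None,
    leave_one_out: bool = False,
) -> list[RiskResult]:
    """Score and classify every sample of a query matrix.

    Probe IDs and order must match the cohort exactly — no silent
    reordering across differently named probes. With ``leave_one_out``
    a query whose sample ID occurs in the reference cohort is scored with
    that reference sample excluded, so its own label never informs its
    prediction.
    """
    params = params or PredictorParams()
    thresholds = thresholds or RiskThresholds()
    if list(queries.probe_ids) != list(cohort.matrix.probe_ids):
        raise ValueError(
            "query matrix probes must match the reference panel probes in order"
        )
    q_ranked = _rank_rows(queries.values.to_numpy(float))
    ref_ranked = _rank_rows(cohort.matrix.values.to_numpy(float))
    rho_all = q_ranked @ ref_ranked.T  # queries × references
    y = cohort.labels.to_numpy(float)
    ref_ids = np.asarray(cohort.matrix.sample_ids)
    results: list[RiskResult] = []
    for i, sid in enumerate(queries.sample_ids):
        if np.ptp(queries.values.iloc[i].to_numpy()) == 0:
            raise ValueError(f"constant query profile for sample {sid!r}")
        mask = ref_ids != sid if leave_one_out else np.ones(len(ref_ids), bool)
        p, fallback, _ = _posterior_from_correlations(rho_all[i, mask], y[mask], params)
        results.append(
            RiskResult(
                sample_id=sid,
                p=p,
                risk_class=classify_risk(p, thresholds),
                prior_fallback=fallback,
            )
        )
    return results


def results_to_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Tabulate RiskResults as a DataFrame indexed by sample ID."""
    return pd.DataFrame(
        {
            "p": [r.p for r in results],
            "risk_class": [r.risk_class for r in results],
            "prior_fallback": [r.prior_fallback for r in results],
        },
        index=[r.sample_id for r in results],
    ).rename_axis("sample_id")
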