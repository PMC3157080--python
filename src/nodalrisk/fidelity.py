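"""The "high fidelity" probe screen.

Microarray probes behave differently on formalin-fixed paraffin-embedded
(FFPE) versus fresh-frozen (FF) RNA, and may shift between transurethral
resection (TUR) and cystectomy specimens. A probe is retained as *high
fidelity* when both of two per-probe criteria hold:

1. its expression correlates positively across matched FFPE–FF sample pairs
   (one-tailed test of r > 0 at alpha = 0.025 by default), and
2. its expression does not differ significantly between independent TUR and
   cystectomy specimen groups (two-tailed test, retained when p >= 0.01 by
   default).

The correlation is Pearson on the log-scale values with the one-tailed p
from the t-transform of r at n - 2 degrees of freedom (Spearman available
via ``method="spearman"``); the group comparison is a Welch two-sample
t-test. No multiple-testing correction is applied across probes — the
criteria are stated per probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nodalrisk.io import ExpressionMatrix

__all__ = [
    "DegenerateInputError",
    "FidelityCriteria",
    "paired_correlation_test",
    "specimen_equivalence_test",
    "screen_panel",
]


class DegenerateInputError(ValueError):
    """Raised when a probe's values carry no variance where variance is required."""


@dataclass(frozen=True)
class FidelityCriteria:
    """Significance levels of the two-part probe screen.

    alpha_corr : one-tailed level for the FFPE/FF correlation test (default 0.025).
    alpha_diff : two-tailed level for the TUR/cystectomy difference test
        (default 0.01); a probe passes when it *fails to reject* at this level.
    """

    alpha_corr: float = 0.025
    alpha_diff: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha_corr", "alpha_diff"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1); got {a}")


def _paired_probe_values(
    ffpe: ExpressionMatrix, ff: ExpressionMatrix, probe_id: str
) -> tuple[np.ndarray, np.ndarray]:
    if set(ffpe.sample_ids) != set(ff.sample_ids):
        raise ValueError(
            "FFPE and FF matrices must contain the same sample IDs (matched pairs)"
        )
    x = ffpe.probe_values(probe_id)
    y = ff.probe_values(probe_id).reindex(x.index)
    return x.to_numpy(float), y.to_numpy(float)


def paired_correlation_test(
    ffpe: ExpressionMatrix,
    ff: ExpressionMatrix,
    probe_id: str,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation of one probe across matched FFPE–FF pairs, with one-tailed p.

    Tests H0: r <= 0 against H1: r > 0. Pairs are matched by sample ID.
    Returns ``(r, p_one_tailed)``.
    """
    x, y = _paired_probe_values(ffpe, ff, probe_id)
    if len(x) < 3:
        raise ValueError(f"need >= 3 matched pairs; got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            f"probe {probe_id!r} has zero variance in FFPE or FF values"
        )
    if method == "pearson":
        res = stats.pearsonr(x, y, alternative="greater")
    elif method == "spearman":
        res = stats.spearmanr(x, y, alternative="greater")
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def specimen_equivalence_test(
    tur: ExpressionMatrix,
    cyst: ExpressionMatrix,
    probe_id: str,
) -> float:
    """Two-tailed p-value for a TUR-vs-cystectomy difference in one probe.

    Welch two-sample t-test on independent groups (unequal n and variance
    allowed). Identical constant groups return p = 1; a constant-but-shifted
    pair of groups returns p = 0.
    """
    x = tur.probe_values(probe_id).to_numpy(float)
    y = cyst.probe_values(probe_id).to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"each specimen group needs >= 2 samples; got {len(x)} and {len(y)}"
        )
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def screen_panel(
    ffpe: ExpressionMatrix,
    ff: ExpressionMatrix,
    tur: ExpressionMatrix,
    cyst: ExpressionMatrix,
    probes: Sequence[str],
    criteria: FidelityCriteria | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """Run the full high-fidelity screen over a list of probes.

    Returns one row per probe with columns ``r``, ``p_corr``, ``p_diff``,
    ``pass_corr``, ``pass_diff``, ``pass_overall`` and ``reason``. A probe
    passes overall iff p_corr < alpha_corr AND p_diff >= alpha_diff.
    Degenerate probes (zero variance) fail automatically with a reason code
    instead of raising.
    """
    criteria = criteria or FidelityCriteria()
    rows = []
    for probe in probes:
        r: float = np.nan
        p_corr: float = np.nan
        p_diff: float = np.nan
        reason = ""
        try:
            r, p_corr = paired_correlation_test(ffpe, ff, probe, method=method)
            pass_corr = bool(p_corr < criteria.alpha_corr)
        except DegenerateInputError:
            pass_corr = False
            reason = "zero-variance-pairs"
        try:
            p_diff = specimen_equivalence_test(tur, cyst, probe)
            pass_diff = bool(p_diff >= criteria.alpha_diff)
        except ValueError as exc:
            pass_diff = False
            reason = (reason + ";" if reason else "") + f"diff-test:{exc}"
        rows.append(
            {
                "probe_id": probe,
                "r": r,
                "p_corr": p_corr,
                "p_diff": p_diff,
                "pass_corr": pass_corr,
                "pass_diff": pass_diff,
                "pass_overall": pass_corr and pass_diff,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")
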