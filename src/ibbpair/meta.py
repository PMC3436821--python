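"""Classical combinations of 2x2 tables: Mantel-Haenszel and DerSimonian-Laird.

Both are the standard meta-analysis baselines for stratified count tables.
Mantel-Haenszel is a fixed-effect test (one common effect, no between-pair
heterogeneity); DerSimonian-Laird is a random-effects model on per-pair log
fold changes with a moment-estimated between-pair variance.  On data with
opposite per-pair regulation MH can return extreme significance, which is the
behaviour the inverted beta-binomial model is designed to avoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

from .tables import DEFAULT_CORRECTION, PairedCountTable

__all__ = ["MetaResult", "mh_test", "dsl_test"]


@dataclass(frozen=True)
class MetaResult:
    """Combined effect and significance from a classical stratified method."""

    method: str  # "MH" or "DSL"
    common_effect: float  # relative-risk / fold-change scale
    statistic: float
    p_value: float
    tau2: float = 0.0  # between-pair variance (DSL only)
    n_strata: int = 0


def mh_test(tables: Sequence[PairedCountTable]) -> MetaResult:
    """Cochran-Mantel-Haenszel chi-square (1 df, no continuity correction)
    plus the Mantel-Haenszel common relative risk across the N strata."""
    if len(tables) < 1:
        raise ValueError("need at least one stratum")
    kept = []
    for t in tables:
        if t.before + t.after == 0:
            warnings.warn(
                f"stratum {t.subject_id!r} has a zero pair total and was skipped",
                stacklevel=2,
            )
            continue
        kept.append(t)
    if not kept:
        raise ValueError("all strata have zero totals")
    # rows = condition (before, after), columns = (feature, all others):
    # row risks a/t_a vs b/t_b, so the pooled risk ratio is the common fold change
    stack = np.array(
        [[[t.before, t.others_before], [t.after, t.others_after]] for t in kept]
    ).transpose(1, 2, 0)
    st = StratifiedTable(stack.astype(float))
    res = st.test_null_odds(correction=False)
    return MetaResult(
        method="MH",
        common_effect=float(st.riskratio_pooled),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tau2=0.0,
        n_strata=len(kept),
    )


def dsl_test(
    tables: Sequence[PairedCountTable], correction: float = DEFAULT_CORRECTION
) -> MetaResult:
    """DerSimonian-Laird random-effects combination of per-pair log fold changes.

    Per pair, the log fold change and its sampling variance
    1/a + 1/b + 1/c + 1/d are computed from the 2x2 cells; any table with a
    zero cell first gets ``correction`` added to all four cells.  tau^2 is
    the classic moment estimator from Cochran's Q (clamped at zero); with a
    single stratum the result reduces to a fixed-effect Wald z-test.
    """
    if len(tables) < 1:
        raise ValueError("need at least one stratum")
    if correction < 0:
        raise ValueError("correction must be non-negative")
    effects, variances = [], []
    for t in tables:
        cells = np.array(
            [t.before, t.after, t.others_before, t.others_after], dtype=float
        )
        if np.any(cells == 0):
            cells = cells + correction
        a, b, c, d = cells
        log_f = np.log((a / (a + c)) / (b / (b + d)))
        effects.append(log_f)
        variances.append(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    effects = np.asarray(effects)
    variances = np.asarray(variances)
    if len(tables) == 1:
        z = effects[0] / np.sqrt(variances[0])
        return MetaResult(
            method="DSL",
            common_effect=float(np.exp(effects[0])),
            statistic=float(z),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
            tau2=0.0,
            n_strata=1,
        )
    with warnings.catch_warnings():
        # combine_effects takes sqrt of the unclamped tau2 internally
        warnings.simplefilter("ignore", RuntimeWarning)
        combined = combine_effects(effects, variances, method_re="dl")
    tau2 = max(0.0, float(combined.tau2))  # moment estimator clamped at zero
    weights = 1.0 / (variances + tau2)
    mean = float(np.sum(weights * effects) / np.sum(weights))
    se = float(np.sqrt(1.0 / np.sum(weights)))
    z = mean / se
    return MetaResult(
        method="DSL",
        common_effect=float(np.exp(mean)),
        statistic=float(z),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        tau2=tau2,
        n_strata=len(tables),
    )
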