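"""Maximum-likelihood fitting and the likelihood-ratio test.

The full model has free beta shapes (alpha, beta); the null constrains
alpha = beta, i.e. a common fold change of one.  The test statistic is
S = 2 * (l_full - l_null), referred to a chi-square distribution with one
degree of freedom, and alpha_hat / beta_hat estimates the common fold
change.  Optimization runs in (log alpha, log beta) inside a fixed box;
features whose counts are all zero on one side push the optimum to the box
boundary and are flagged (the reported p-value is then conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import DEFAULT_ORDER, QuadratureRule, _loglik_and_score
from .tables import (
    DEFAULT_CORRECTION,
    CountMatrix,
    FeaturePairSet,
    PairingDesign,
    build_pair_sets,
    observed_fold_change,
)

__all__ = [
    "IbbResult",
    "ForestRecord",
    "fit_full",
    "fit_null",
    "ibb_test",
    "confidence_interval",
    "per_pair_estimates",
    "test_all_features",
]

#: box bounds on log(alpha), log(beta)
LOG_BOUND = 10.0

#: convergence tolerances handed to the optimizer
_FTOL = 1e-12
_GTOL = 1e-8


@dataclass
class IbbResult:
    """Result of the paired-sample test for one feature."""

    feature_id: str
    alpha_hat: float
    beta_hat: float
    fold_change: float
    log_lik_full: float
    log_lik_null: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool
    at_bound: bool
    untestable: bool
    v: float
    n_pairs: int
    p_adjusted: float = field(default=np.nan)


@dataclass(frozen=True)
class ForestRecord:
    """One row of a forest plot: a per-subject or combined log fold change."""

    label: str
    log_fold: float
    ci_low: float
    ci_high: float
    weight: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.log_fold <= self.ci_high):
            raise ValueError("point estimate must lie inside its interval")


@dataclass(frozen=True)
class _Fit:
    alpha: float
    beta: float
    log_lik: float
    converged: bool
    at_bound: bool


def _moment_start(pairs: FeaturePairSet) -> np.ndarray:
    """Method-of-moments start from per-pair corrected fold changes."""
    u = []
    for p in pairs.pairs:
        phi = observed_fold_change(p, DEFAULT_CORRECTION)
        u.append(phi / (1.0 + phi))
    u = np.asarray(u)
    m = float(np.clip(u.mean(), 1e-4, 1.0 - 1e-4))
    var = float(u.var()) if len(u) > 1 else m * (1.0 - m) / 10.0
    var = max(var, 1e-6)
    lam = np.clip(m * (1.0 - m) / var - 1.0, 0.1, 1e4)
    return np.clip(np.log([m * lam, (1.0 - m) * lam]), -LOG_BOUND, LOG_BOUND)


def fit_null(
    pairs: FeaturePairSet,
    v: float = 1.0,
    rule: QuadratureRule | None = None,
) -> _Fit:
    """One-dimensional fit under the constraint alpha = beta."""
    order = rule.order if rule is not None else DEFAULT_ORDER

    def nll(theta: float) -> float:
        a = float(np.exp(theta))
        total, _, _ = _loglik_and_score(pairs, a, a, v, order)
        return -total

    grid = np.linspace(-LOG_BOUND, LOG_BOUND, 41)
    values = [nll(t) for t in grid]
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    theta = float(res.x) if res.fun <= values[k] else float(grid[k])
    ll = -min(float(res.fun), values[k])
    alpha = float(np.exp(theta))
    at_bound = abs(theta) >= LOG_BOUND - 1e-3
    return _Fit(alpha, alpha, ll, bool(res.success), at_bound)


def fit_full(
    pairs: FeaturePairSet,
    v: float = 1.0,
    rule: QuadratureRule | None = None,
) -> _Fit:
    """Unconstrained fit of (alpha, beta) by multi-start bounded quasi-Newton."""
    order = rule.order if rule is not None else DEFAULT_ORDER

    def nll_grad(theta: np.ndarray):
        a, b = np.exp(theta)
        total, da, db = _loglik_and_score(pairs, float(a), float(b), v, order)
        # chain rule to log-parameters
        return -total, -np.array([da * a, db * b])

    null = fit_null(pairs, v, rule)
    theta_null = np.log(null.alpha)
    starts = [
        np.array([0.0, 0.0]),
        _moment_start(pairs),
        np.array([theta_null, theta_null]),
        np.array([6.0, 6.0]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-LOG_BOUND, LOG_BOUND)] * 2,
            options={"ftol": _FTOL, "gtol": _GTOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    alpha, beta = np.exp(best.x)
    ll = -float(best.fun)
    if ll < null.log_lik:  # nested models: never worse than the null optimum
        alpha = beta = null.alpha
        ll = null.log_lik
    at_bound = bool(np.any(np.abs(best.x) >= LOG_BOUND - 1e-3))
    return _Fit(float(alpha), float(beta), ll, bool(best.success), at_bound)


def _hessian_log_params(
    pairs: FeaturePairSet, fit: _Fit, v: float, order: int, step: float = 1e-4
) -> np.ndarray:
    """Observed information in (log alpha, log beta) by central differences
    of the analytic score."""
    theta = np.log([fit.alpha, fit.beta])

    def grad(th: np.ndarray) -> np.ndarray:
        a, b = np.exp(th)
        _, da, db = _loglik_and_score(pairs, float(a), float(b), v, order)
        return -np.array([da * a, db * b])

    H = np.zeros((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = step
        H[:, j] = (grad(theta + e) - grad(theta - e)) / (2.0 * step)
    return 0.5 * (H + H.T)


def confidence_interval(
    pairs: FeaturePairSet,
    result: IbbResult,
    level: float = 0.95,
    rule: QuadratureRule | None = None,
) -> tuple[float, float]:
    """Wald interval for the common fold change from the observed information.

    The Hessian is taken at the optimum in (log alpha, log beta); the delta
    method gives the variance of log(alpha/beta), which is exponentiated.
    A singular Hessian (typically a boundary fit) yields infinite bounds.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    order = rule.order if rule is not None else DEFAULT_ORDER
    fit = _Fit(result.alpha_hat, result.beta_hat, result.log_lik_full,
               result.converged, result.at_bound)
    H = _hessian_log_params(pairs, fit, result.v, order)
    contrast = np.array([1.0, -1.0])
    try:
        cov_c = contrast @ np.linalg.solve(H, contrast)
    except np.linalg.LinAlgError:
        cov_c = np.inf
    if not np.isfinite(cov_c) or cov_c <= 0:
        return 0.0, np.inf
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_fc = np.log(result.fold_change)
    half = z * np.sqrt(cov_c)
    return float(np.exp(log_fc - half)), float(np.exp(log_fc + half))


def ibb_test(
    pairs: FeaturePairSet,
    v: float = 1.0,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
) -> IbbResult:
    """Inverted beta-binomial likelihood-ratio test for one feature."""
    if all(p.before == 0 and p.after == 0 for p in pairs.pairs):
        return IbbResult(
            feature_id=pairs.feature_id,
            alpha_hat=np.nan, beta_hat=np.nan, fold_change=np.nan,
            log_lik_full=0.0, log_lik_null=0.0, statistic=0.0, p_value=1.0,
            ci_low=np.nan, ci_high=np.nan, converged=False, at_bound=False,
            untestable=True, v=v, n_pairs=pairs.n_pairs,
        )
    full = fit_full(pairs, v, rule)
    null = fit_null(pairs, v, rule)
    statistic = 2.0 * (full.log_lik - null.log_lik)
    statistic = max(statistic, 0.0)
    p_value = float(stats.chi2.sf(statistic, df=1))
    result = IbbResult(
        feature_id=pairs.feature_id,
        alpha_hat=full.alpha,
        beta_hat=full.beta,
        fold_change=full.alpha / full.beta,
        log_lik_full=full.log_lik,
        log_lik_null=null.log_lik,
        statistic=float(statistic),
        p_value=p_value,
        ci_low=np.nan,
        ci_high=np.nan,
        converged=full.converged and null.converged,
        at_bound=full.at_bound,
        untestable=False,
        v=v,
        n_pairs=pairs.n_pairs,
    )
    lo, hi = confidence_interval(pairs, result, level, rule)
    result.ci_low, result.ci_high = lo, hi
    return result


def _clopper_pearson(a: int, s: int, level: float) -> tuple[float, float]:
    tail = (1.0 - level) / 2.0
    lo = 0.0 if a == 0 else float(stats.beta.ppf(tail, a, s - a + 1))
    hi = 1.0 if a == s else float(stats.beta.ppf(1.0 - tail, a + 1, s - a))
    return lo, hi


def per_pair_estimates(
    pairs: FeaturePairSet,
    v: float = 1.0,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
    combined: bool = True,
) -> list[ForestRecord]:
    """Forest-plot rows: per-subject log fold changes plus the combined row.

    Point estimates are observed fold changes (pseudo-count 0.5 only when a
    count is zero); intervals come from the exact conditional binomial
    (Clopper-Pearson on the success probability, mapped to the fold-change
    scale); per-subject weights are proportional to the pair total.
    """
    totals = np.array([p.before + p.after for p in pairs.pairs], dtype=float)
    wsum = totals.sum()
    records = []
    for p, s_tot in zip(pairs.pairs, totals):
        corr = DEFAULT_CORRECTION if (p.before == 0 or p.after == 0) else 0.0
        log_fold = float(np.log(observed_fold_change(p, corr)))
        s = p.before + p.after
        if s == 0:
            records.append(ForestRecord(p.subject_id, 0.0, -np.inf, np.inf, 0.0))
            continue
        p_lo, p_hi = _clopper_pearson(p.before, s, level)
        ratio = p.total_after / p.total_before  # phi = p/(1-p) * t_b/t_a
        with np.errstate(divide="ignore"):
            lo = np.log(p_lo) - np.log1p(-p_lo) + np.log(ratio) if p_lo > 0 else -np.inf
            hi = np.log(p_hi) - np.log1p(-p_hi) + np.log(ratio) if p_hi < 1 else np.inf
        weight = float(s_tot / wsum) if wsum > 0 else 0.0
        records.append(ForestRecord(p.subject_id, log_fold, float(lo), float(hi), weight))
    if combined:
        res = ibb_test(pairs, v, rule, level)
        with np.errstate(divide="ignore"):
            lo = np.log(res.ci_low) if res.ci_low > 0 else -np.inf
            hi = np.log(res.ci_high) if np.isfinite(res.ci_high) else np.inf
        records.append(
            ForestRecord("combined", float(np.log(res.fold_change)), lo, hi, 1.0)
        )
    return records


def test_all_features(
    matrix: CountMatrix,
    design: PairingDesign,
    v: float = 1.0,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
) -> list[IbbResult]:
    """Run the test on every matrix feature and attach BH-adjusted p-values.

    Features with zero counts in every sample are reported untestable with
    p = 1 and excluded from the multiplicity adjustment.
    """
    results = [
        ibb_test(ps, v, rule, level) for ps in build_pair_sets(matrix, design)
    ]
    tested = [r for r in results if not r.untestable]
    if tested:
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([r.p_value for r in tested])
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for r, adj in zip(tested, adjusted):
            r.p_adjusted = float(adj)
    for r in results:
        if r.untestable:
            r.p_adjusted = 1.0
    return results
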