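"""Likelihood kernels of the inverted beta-binomial model.

The generative model for one paired table with counts ``(a, b)`` and totals
``(t_a, t_b)`` is

* technical variation: conditional on the pair total ``s = a + b``, the
  before-count ``a`` follows a binomial distribution with success probability
  ``p = phi * t_a / (phi * t_a + t_b)``, where ``phi`` is the true fold
  change (the ratio of two Poisson rates conditioned on their sum); for a
  platform whose technical variance differs from Poisson the binomial pmf is
  raised to a power ``v`` and renormalized over the finite support
  (the exponentiated binomial; ``v < 1`` over-dispersed, ``v > 1``
  under-dispersed),
* biological variation: ``phi = u / (1 - u)`` with ``u ~ Beta(alpha, beta)``,
  i.e. ``phi`` follows an inverted-beta (beta-prime-type) law whose ratio
  ``alpha/beta`` plays the role of the common fold change.

The observed-data likelihood marginalizes ``u`` out.  With equal totals and
``v = 1`` the marginal is the closed-form beta-binomial; otherwise it is a
one-dimensional integral over (0, 1) evaluated here by Gauss-Jacobi
quadrature (``v = 1``) or a tanh-sinh rule (``v != 1``), always in log space.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import linalg, special

from .tables import FeaturePairSet, PairedCountTable

__all__ = [
    "IbbParams",
    "QuadratureRule",
    "success_prob",
    "log_conditional_pmf",
    "gauss_jacobi_rule",
    "log_marginal",
    "log_likelihood",
    "score",
]

#: default Gauss-Jacobi order
DEFAULT_ORDER = 64

LOG_TWO = np.log(2.0)


@dataclass(frozen=True)
class IbbParams:
    """Beta shapes of the random effect plus the technical exponent ``v``."""

    alpha: float
    beta: float
    v: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if not self.v > 0:
            raise ValueError("v must be positive")

    @property
    def fold_change(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Jacobi nodes/weights for weight (1-z)^(a0-1) (1+z)^(b0-1) on [-1, 1]."""

    order: int
    nodes: np.ndarray
    weights: np.ndarray
    log_weights: np.ndarray
    alpha0: float
    beta0: float

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be at least 2")
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")


def _jacobi_log_rule(order: int, exp_one_minus: float, exp_one_plus: float):
    """Golub-Welsch rule for weight (1-z)^A (1+z)^B with log-space weights.

    A and B may be large (the absorbed-exponent path uses A = beta + v*b - 1,
    B = alpha + v*a - 1), where forming the weights in linear scale would
    overflow; the total mass enters through log(mu0) instead.
    """
    A, B = float(exp_one_minus), float(exp_one_plus)
    if A <= -1 or B <= -1:
        raise ValueError("Jacobi exponents must exceed -1")
    apb = A + B
    d = np.empty(order)
    d[0] = (B - A) / (apb + 2.0)
    k = np.arange(1, order)
    d[1:] = (B * B - A * A) / ((2 * k + apb) * (2 * k + apb + 2.0))
    num = 4.0 * k * (k + A) * (k + B) * (k + apb)
    den = (2 * k + apb) ** 2 * (2 * k + apb + 1.0) * (2 * k + apb - 1.0)
    e = np.sqrt(num / den)
    nodes, vec = linalg.eigh_tridiagonal(d, e)
    log_mu0 = (apb + 1.0) * LOG_TWO + special.betaln(A + 1.0, B + 1.0)
    with np.errstate(divide="ignore"):
        log_w = log_mu0 + 2.0 * np.log(np.abs(vec[0, :]))
    return nodes, log_w


def gauss_jacobi_rule(alpha0: float, beta0: float, order: int = DEFAULT_ORDER) -> QuadratureRule:
    """Gauss-Jacobi rule with shape parameters (alpha0 - 1, beta0 - 1).

    Exact for polynomials of degree <= 2*order - 1 against the weight
    ``(1-z)**(alpha0-1) * (1+z)**(beta0-1)`` on [-1, 1].
    """
    if not (alpha0 > 0 and beta0 > 0):
        raise ValueError("shape parameters must be positive")
    if order < 2:
        raise ValueError("order must be at least 2")
    nodes, log_w = _jacobi_log_rule(order, alpha0 - 1.0, beta0 - 1.0)
    return QuadratureRule(
        order=order,
        nodes=nodes,
        weights=np.exp(log_w),
        log_weights=log_w,
        alpha0=alpha0,
        beta0=beta0,
    )


def success_prob(phi: float, total_before: float, total_after: float) -> float:
    """Binomial success probability of the before-count given the pair total.

    Conditioning two Poisson counts with means pi_a*t_a and pi_b*t_b on their
    sum gives a binomial whose single parameter is
    ``phi * t_a / (phi * t_a + t_b)`` with ``phi = pi_a / pi_b``.
    """
    if not phi > 0:
        raise ValueError("phi must be positive")
    if total_before <= 0 or total_after <= 0:
        raise ValueError("totals must be positive")
    x = phi * total_before
    return float(x / (x + total_after))


def _log_binom_coeff(k, s):
    return special.gammaln(s + 1) - special.gammaln(k + 1) - special.gammaln(s - k + 1)


def log_conditional_pmf(a: int, s: int, p: float, v: float = 1.0) -> float:
    """Log pmf of the (exponentiated) binomial technical-variation model.

    For ``v = 1`` this is the binomial pmf.  Otherwise the binomial pmf is
    raised to the power ``v`` and renormalized by a finite log-sum-exp over
    the support {0, ..., s}; the infinite-series normalizer of the underlying
    exponentiated Poisson cancels in the conditioning and never appears.
    """
    if not 0 <= a <= s:
        raise ValueError("need 0 <= a <= s")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if not v > 0:
        raise ValueError("v must be positive")
    logp, log1mp = np.log(p), np.log1p(-p)
    val = v * (_log_binom_coeff(a, s) + a * logp + (s - a) * log1mp)
    if v == 1.0:
        return float(val)
    k = np.arange(s + 1)
    allk = v * (_log_binom_coeff(k, s) + k * logp + (s - k) * log1mp)
    return float(val - special.logsumexp(allk))


# ---------------------------------------------------------------------------
# tanh-sinh rule on (0, 1), used for the exponentiated-binomial marginal
# ---------------------------------------------------------------------------


class _TanhSinhGrid:
    """Fixed tanh-sinh nodes on (0, 1), stored as (log u, log(1-u), log w).

    The double-exponential transform handles the u**(alpha-1) (1-u)**(beta-1)
    endpoint behaviour for any alpha, beta > 0; the step size is small enough
    to resolve posterior bumps down to widths of a few 1e-3, which covers the
    parameter box used by the optimizer.
    """

    def __init__(self, t_max: float = 5.0, step: float = 1e-3) -> None:
        n = int(np.ceil(t_max / step))
        t = np.arange(-n, n + 1) * (t_max / n)
        q = 0.5 * np.pi * np.sinh(t)
        self.log_u = -np.logaddexp(0.0, -2.0 * q)
        self.log_1mu = -np.logaddexp(0.0, 2.0 * q)
        self.log_w = (
            np.log(np.pi / 4.0)
            + np.log(np.cosh(t))
            - 2.0 * np.log(np.cosh(q))
            + np.log(t_max / n)
        )


@functools.lru_cache(maxsize=1)
def _ts_grid() -> _TanhSinhGrid:
    return _TanhSinhGrid()


@functools.lru_cache(maxsize=512)
def _ts_conditional(a: int, b: int, t_a: float, t_b: float, v: float) -> np.ndarray:
    """log conditional pmf of ``a`` at every tanh-sinh node (independent of alpha, beta)."""
    grid = _ts_grid()
    s = a + b
    log_r = np.log(t_a) - np.log(t_b)
    log_den = np.logaddexp(log_r + grid.log_u, grid.log_1mu)
    logp = log_r + grid.log_u - log_den
    log1mp = grid.log_1mu - log_den
    val = v * (_log_binom_coeff(a, s) + a * logp + b * log1mp)
    if v != 1.0:
        k = np.arange(s + 1)
        lk = v * _log_binom_coeff(k, s)
        mat = lk[None, :] + v * (k[None, :] * logp[:, None] + (s - k)[None, :] * log1mp[:, None])
        val = val - special.logsumexp(mat, axis=1)
    return val


def _gj_order(order: int, s: float, t_a: float, t_b: float) -> int:
    # the smooth residual (1 + (r-1)u)^(-s) oscillates over the posterior bump
    # with phase ~ sqrt(s)*|log r|; scale the rule accordingly
    phase = np.sqrt(max(s, 1.0)) * abs(np.log(t_a / t_b))
    return int(min(max(order, 32 + 3 * phase), 2000))


def _log_marginal_one(
    a: int, b: int, t_a: float, t_b: float, alpha: float, beta: float, v: float,
    order: int, method: str,
) -> tuple[float, float, float]:
    """Log marginal of one table plus posterior moments E[log u], E[log(1-u)].

    The moments feed the analytic score: d(log m)/d(alpha) =
    E[log u] - psi(alpha) + psi(alpha+beta), and symmetrically for beta.
    """
    s = a + b
    if s == 0:
        # conditional on a zero pair total the distribution is a point mass;
        # the posterior of u is the prior
        return 0.0, special.digamma(alpha) - special.digamma(alpha + beta), special.digamma(
            beta
        ) - special.digamma(alpha + beta)

    if method == "auto":
        if v == 1.0 and t_a == t_b:
            method = "closed_form"
        elif v == 1.0:
            method = "jacobi"
        else:
            method = "tanh_sinh"

    if method == "closed_form":
        if v != 1.0 or t_a != t_b:
            raise ValueError("closed form requires v = 1 and equal totals")
        lm = (
            _log_binom_coeff(a, s)
            + special.betaln(a + alpha, b + beta)
            - special.betaln(alpha, beta)
        )
        e_logu = special.digamma(a + alpha) - special.digamma(s + alpha + beta)
        e_log1mu = special.digamma(b + beta) - special.digamma(s + alpha + beta)
        return float(lm), float(e_logu), float(e_log1mu)

    if method == "jacobi":
        if v != 1.0:
            raise ValueError("the Gauss-Jacobi path requires v = 1")
        m = _gj_order(order, s, t_a, t_b)
        nodes, log_w = _jacobi_log_rule(m, beta + b - 1.0, alpha + a - 1.0)
        u = 0.5 * (1.0 + nodes)
        r = t_a / t_b
        terms = log_w - s * np.log1p((r - 1.0) * u)
        lse = special.logsumexp(terms)
        lm = (
            lse
            + _log_binom_coeff(a, s)
            + a * np.log(r)
            - (alpha + beta + s - 1.0) * LOG_TWO
            - special.betaln(alpha, beta)
        )
        post = np.exp(terms - lse)
        log_u = np.log(u)
        log_1mu = np.log1p(-u)
    elif method == "tanh_sinh":
        grid = _ts_grid()
        lcond = _ts_conditional(int(a), int(b), float(t_a), float(t_b), float(v))
        terms = (
            grid.log_w
            + lcond
            + (alpha - 1.0) * grid.log_u
            + (beta - 1.0) * grid.log_1mu
            - special.betaln(alpha, beta)
        )
        lm = special.logsumexp(terms)
        post = np.exp(terms - lm)
        log_u = grid.log_u
        log_1mu = grid.log_1mu
    else:
        raise ValueError(f"unknown method {method!r}")

    e_logu = float(post @ log_u)
    e_log1mu = float(post @ log_1mu)
    return float(lm), e_logu, e_log1mu


def log_marginal(
    table: PairedCountTable,
    params: IbbParams,
    rule: QuadratureRule | None = None,
    method: str = "auto",
) -> float:
    """Log marginal probability of one paired table given the pair total.

    ``method`` selects the evaluation path: "auto" (closed-form beta-binomial
    when v = 1 and totals are equal, Gauss-Jacobi for v = 1 with unequal
    totals, tanh-sinh otherwise), or one of "closed_form", "jacobi",
    "tanh_sinh" explicitly.
    """
    order = rule.order if rule is not None else DEFAULT_ORDER
    lm, _, _ = _log_marginal_one(
        table.before,
        table.after,
        float(table.total_before),
        float(table.total_after),
        params.alpha,
        params.beta,
        params.v,
        order,
        method,
    )
    return lm


def _loglik_and_score(
    pairs: FeaturePairSet,
    alpha: float,
    beta: float,
    v: float,
    order: int,
    method: str = "auto",
) -> tuple[float, float, float]:
    """Total log likelihood and its gradient with respect to (alpha, beta)."""
    total = 0.0
    sum_elogu = 0.0
    sum_elog1mu = 0.0
    n = 0
    for p in pairs.pairs:
        lm, e1, e2 = _log_marginal_one(
            p.before, p.after, float(p.total_before), float(p.total_after),
            alpha, beta, v, order, method,
        )
        total += lm
        sum_elogu += e1
        sum_elog1mu += e2
        n += 1
    psi_ab = special.digamma(alpha + beta)
    d_alpha = sum_elogu - n * (special.digamma(alpha) - psi_ab)
    d_beta = sum_elog1mu - n * (special.digamma(beta) - psi_ab)
    return total, d_alpha, d_beta


def log_likelihood(
    pairs: FeaturePairSet,
    params: IbbParams,
    rule: QuadratureRule | None = None,
    method: str = "auto",
) -> float:
    """Sum of log marginals over the N pairs of one feature."""
    order = rule.order if rule is not None else DEFAULT_ORDER
    total, _, _ = _loglik_and_score(pairs, params.alpha, params.beta, params.v, order, method)
    return total


def score(
    pairs: FeaturePairSet,
    params: IbbParams,
    rule: QuadratureRule | None = None,
) -> np.ndarray:
    """Gradient of the log likelihood with respect to (alpha, beta)."""
    order = rule.order if rule is not None else DEFAULT_ORDER
    _, da, db = _loglik_and_score(pairs, params.alpha, params.beta, params.v, order)
    return np.array([da, db])
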