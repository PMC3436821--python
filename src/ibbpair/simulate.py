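"""Synthetic paired count data.

Three generators:

* Poisson pairs — the basic technical-variation model: independent counts
  with means pi_a * t_a and pi_b * t_b.
* The normal-approximation experiment — many Poisson pairs at a single small
  observation, showing that the histogram of log fold changes is multimodal
  and poorly matched by the normal approximation built on the
  1/a + 1/b + 1/c + 1/d variance.
* Inverted beta-binomial datasets — the full generative chain
  u ~ Beta(alpha, beta), phi = u/(1-u), a | s ~ (exponentiated) binomial —
  conditioned on per-pair totals so that the conditional likelihood of the
  fitted model matches the generator exactly.  An unconditional mode draws
  both margins as Poisson for end-to-end pipeline tests.

All generators are deterministic given (seed, configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, special

from .model import _log_binom_coeff
from .tables import FeaturePairSet, PairedCountTable

__all__ = [
    "SimulationConfig",
    "simulate_poisson_pair",
    "NormalApproxResult",
    "normal_approximation_experiment",
    "simulate_ibb_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the dataset generator."""

    alpha: float = 8.0
    beta: float = 8.0
    v: float = 1.0
    n_pairs: int = 5
    n_features: int = 1
    total_before: int = 100_000
    total_after: int = 100_000
    pi_before: float = 1e-4
    pi_after: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.v > 0):
            raise ValueError("alpha, beta and v must be positive")
        if self.n_pairs < 1 or self.n_features < 1:
            raise ValueError("need at least one pair and one feature")
        if not (0 < self.pi_before < 1 and 0 < self.pi_after < 1):
            raise ValueError("true fractions must lie in (0, 1)")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for stochastic operations")
    return np.random.default_rng(seed)


def simulate_poisson_pair(
    pi_before: float,
    pi_after: float,
    total_before: int,
    total_after: int,
    seed,
    subject_id: str = "sim",
) -> PairedCountTable:
    """One paired table with Poisson counts at means pi*total."""
    rng = _rng(seed)
    a = int(rng.poisson(pi_before * total_before))
    b = int(rng.poisson(pi_after * total_after))
    return PairedCountTable(a, b, total_before, total_after, subject_id)


@dataclass(frozen=True)
class NormalApproxResult:
    """Histogram of simulated log fold changes and two normal references."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    sim_mean: float  # mean/sd of the simulated log fold changes
    sim_sd: float
    analytic_mean: float  # observed log f and the 1/a+1/b+1/c+1/d variance
    analytic_sd: float
    ks_distance: float  # sup |ECDF - Normal(sim_mean, sim_sd)|
    n_modes: int
    reps: int


def _count_modes(counts: np.ndarray) -> int:
    """Local maxima of the histogram with a small prominence floor."""
    if counts.max() == 0:
        return 0
    peaks, _ = signal.find_peaks(counts, prominence=0.01 * counts.max())
    interior = len(peaks)
    # find_peaks ignores boundary bins; count a dominant edge bin as a mode
    if len(counts) >= 2 and counts[0] > counts[1]:
        interior += 1
    if len(counts) >= 2 and counts[-1] > counts[-2]:
        interior += 1
    return interior


def normal_approximation_experiment(
    reps: int,
    seed,
    a_obs: int = 2,
    b_obs: int = 8,
    total: int = 30_000,
    correction: float = 0.5,
    bin_width: float = 0.1,
) -> NormalApproxResult:
    """Replicate Poisson pairs at an observed table and bin the log fold changes.

    Counts are drawn with rates a_obs/total and b_obs/total; the log fold
    change of each replicate adds ``correction`` to all four table cells.
    The returned normal parameters are (i) the moment fit to the simulated
    values and (ii) the analytic approximation at the observed table with
    the 1/a + 1/b + 1/c + 1/d variance; the KS distance quantifies how badly
    the moment-fit normal tracks the multimodal histogram.
    """
    if reps < 10_000:
        raise ValueError("need at least 1e4 replicates")
    rng = _rng(seed)
    a = rng.poisson(float(a_obs), size=reps) + correction
    b = rng.poisson(float(b_obs), size=reps) + correction
    c = total - a + 2.0 * correction  # cells after adding the correction
    d = total - b + 2.0 * correction
    log_f = np.log((a / (a + c)) / (b / (b + d)))

    lo = np.floor(log_f.min() / bin_width) * bin_width
    hi = np.ceil(log_f.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    counts, edges = np.histogram(log_f, bins=edges)

    sim_mean = float(log_f.mean())
    sim_sd = float(log_f.std())
    aa, bb = a_obs + correction, b_obs + correction
    cc, dd = total - a_obs + correction, total - b_obs + correction
    analytic_mean = float(np.log((aa / (aa + cc)) / (bb / (bb + dd))))
    analytic_sd = float(np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd))

    xs = np.sort(log_f)
    ecdf_hi = np.arange(1, reps + 1) / reps
    ecdf_lo = np.arange(0, reps) / reps
    cdf = 0.5 * (1.0 + special.erf((xs - sim_mean) / (sim_sd * np.sqrt(2.0))))
    ks = float(max(np.abs(ecdf_hi - cdf).max(), np.abs(ecdf_lo - cdf).max()))

    return NormalApproxResult(
        bin_edges=edges,
        bin_counts=counts,
        sim_mean=sim_mean,
        sim_sd=sim_sd,
        analytic_mean=analytic_mean,
        analytic_sd=analytic_sd,
        ks_distance=ks,
        n_modes=_count_modes(counts),
        reps=reps,
    )


def _sample_exponentiated_binomial(
    rng: np.random.Generator, s: int, p: np.ndarray, v: float
) -> np.ndarray:
    """Exact inversion sampling over the finite support {0..s} for v != 1."""
    k = np.arange(s + 1)
    lk = v * _log_binom_coeff(k, s)
    logits = lk[None, :] + v * (
        k[None, :] * np.log(p)[:, None] + (s - k)[None, :] * np.log1p(-p)[:, None]
    )
    logits -= special.logsumexp(logits, axis=1, keepdims=True)
    cdf = np.cumsum(np.exp(logits), axis=1)
    udraw = rng.random(size=(len(p), 1))
    return (udraw > cdf).sum(axis=1).clip(0, s)


def simulate_ibb_dataset(
    config: SimulationConfig,
    pair_total: int | np.ndarray = 100,
    mode: str = "conditional",
) -> list[FeaturePairSet]:
    """Datasets from the inverted beta-binomial generative chain.

    In "conditional" mode each pair's total count s is fixed (scalar or a
    length-n_pairs array) and the before-count is drawn from the
    (exponentiated) binomial given s — the same conditional law the test
    fits, making parameter recovery a clean oracle.  In "unconditional" mode
    both counts are Poisson draws (v must be 1), exercising the full
    pipeline including random pair totals.
    """
    rng = _rng(config.seed)
    n_feat, n_pairs = config.n_features, config.n_pairs
    t_a, t_b = config.total_before, config.total_after
    u = rng.beta(config.alpha, config.beta, size=(n_feat, n_pairs))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    p = u * t_a / (u * t_a + (1.0 - u) * t_b)

    if mode == "conditional":
        s = np.broadcast_to(np.asarray(pair_total, dtype=int), (n_pairs,))
        a = np.empty((n_feat, n_pairs), dtype=int)
        for j in range(n_pairs):
            if config.v == 1.0:
                a[:, j] = rng.binomial(int(s[j]), p[:, j])
            else:
                a[:, j] = _sample_exponentiated_binomial(
                    rng, int(s[j]), p[:, j], config.v
                )
        b = s[None, :] - a
    elif mode == "unconditional":
        if config.v != 1.0:
            raise ValueError("unconditional sampling is defined for v = 1 only")
        phi = u / (1.0 - u)
        a = rng.poisson(phi * config.pi_after * t_a)
        b = rng.poisson(config.pi_after * t_b, size=(n_feat, n_pairs))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = []
    for i in range(n_feat):
        pairs = tuple(
            PairedCountTable(int(a[i, j]), int(b[i, j]), t_a, t_b, f"subject{j + 1}")
            for j in range(n_pairs)
        )
        out.append(FeaturePairSet(f"feature{i + 1}", pairs))
    return out
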