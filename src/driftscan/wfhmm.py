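"""Wright-Fisher hidden Markov model for temporal allele-frequency series.

The population allele frequency is a hidden Markov chain on a discrete state
space: allele counts 0..2*Ne (exact mode) or a reduced frequency grid (grid
mode, for large Ne).  One generation of drift-plus-selection moves count k to
Binomial(2*Ne, p') with p' = p(1+s)/(1+ps); states 0 and 2*Ne are absorbing.
Observed allele counts at each sampling time are binomial draws from the
hidden frequency, which accounts for the noise from finite sample sizes.

Per SNP, a likelihood-ratio test compares the maximized-selection model
against neutrality (s = 0), referred to a chi-square(1) upper tail.  The
effective population size is estimated beforehand by maximizing the summed
neutral log-likelihood across loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from driftscan.syndata import selection_update
from driftscan.temporal import TemporalCounts

logger = logging.getLogger(__name__)

#: exact allele-count state space up to this 2*Ne; reduced grid beyond
EXACT_STATE_LIMIT = 400
#: grid size used in grid mode
DEFAULT_GRID_SIZE = 201

#: default selection-coefficient search grid (must contain 0)
DEFAULT_S_GRID = (-0.9, -0.5, -0.3, -0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 0.9)


def default_n_states(ne: int) -> int:
    two_ne = 2 * ne
    return two_ne + 1 if two_ne <= EXACT_STATE_LIMIT else DEFAULT_GRID_SIZE


def build_transition(ne: int, s: float, n_states: int | None = None) -> np.ndarray:
    """One-generation transition matrix of the Wright-Fisher chain.

    Exact mode (``n_states == 2*ne + 1``): row k holds the Binomial(2*ne,
    p'(k/2ne, s)) probability masses.  Grid mode (``n_states < 2*ne + 1``):
    the same binomial mass is aggregated onto the nearest grid frequencies
    (via the binomial CDF at grid midpoints), preserving row-stochasticity.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if s <= -1.0:
        raise ValueError("s must be > -1 (fitness must stay positive)")
    two_ne = 2 * ne
    if n_states is None:
        n_states = default_n_states(ne)
    if n_states < 3:
        raise ValueError("need at least 3 states")
    if n_states > two_ne + 1:
        raise ValueError("n_states cannot exceed 2*ne + 1")

    freqs = state_frequencies(ne, n_states)
    p_next = selection_update(freqs, s)
    if n_states == two_ne + 1:
        counts = np.arange(two_ne + 1)
        T = stats.binom.pmf(counts[None, :], two_ne, p_next[:, None])
    else:
        # count-space boundaries at midpoints between grid frequencies
        mids = 0.5 * (freqs[1:] + freqs[:-1]) * two_ne
        bounds = np.concatenate([[-1.0], np.floor(mids + 0.5) - 0.5, [two_ne + 0.5]])
        cdf = stats.binom.cdf(bounds[None, :], two_ne, p_next[:, None])
        T = np.diff(cdf, axis=1)
    # absorbing boundaries exactly
    T[0] = 0.0
    T[0, 0] = 1.0
    T[-1] = 0.0
    T[-1, -1] = 1.0
    T /= T.sum(axis=1, keepdims=True)
    return T


def state_frequencies(ne: int, n_states: int | None = None) -> np.ndarray:
    """Hidden-state allele frequencies (equispaced on [0, 1])."""
    if n_states is None:
        n_states = default_n_states(ne)
    return np.linspace(0.0, 1.0, n_states)


@dataclass
class WrightFisherModel:
    """Discrete Wright-Fisher HMM with cached transition-matrix powers."""

    ne: int
    s: float
    n_states: int | None = None
    _powers: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.n_states is None:
            self.n_states = default_n_states(self.ne)
        self.freqs = state_frequencies(self.ne, self.n_states)
        self.transition = _cached_transition(self.ne, float(self.s), self.n_states)
        self._powers[1] = self.transition

    def transition_power(self, gap: int) -> np.ndarray:
        """Transition over ``gap`` generations, by repeated multiplication."""
        if gap < 1:
            raise ValueError("gap must be >= 1")
        if gap not in self._powers:
            self._powers[gap] = self.transition_power(gap - 1) @ self.transition
        return self._powers[gap]


@lru_cache(maxsize=512)
def _cached_transition(ne: int, s: float, n_states: int) -> np.ndarray:
    return build_transition(ne, s, n_states)


def _emissions(
    counts: np.ndarray, totals: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Emission matrix for one SNP: (n_obs, n_states) binomial pmfs.

    Generations with total == 0 carry no information: emission 1 everywhere.
    """
    E = stats.binom.pmf(counts[:, None], totals[:, None], freqs[None, :])
    E[totals == 0] = 1.0
    return E


def forward_loglik(
    counts: np.ndarray,
    totals: np.ndarray,
    generations: np.ndarray,
    model: WrightFisherModel,
    init: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one SNP's count series under the model.

    Standard scaled forward recursion; emission at a sampled generation is
    Binomial(total, state frequency) at the observed count, and the
    transition between consecutive observations is the one-generation matrix
    raised to the gap.  ``init`` defaults to uniform over states.
    """
    counts = np.asarray(counts, dtype=int)
    totals = np.asarray(totals, dtype=int)
    generations = np.asarray(generations, dtype=int)
    if counts.size == 0:
        raise ValueError("empty series")
    if np.any(counts > totals):
        raise ValueError("count exceeds total")
    E = _emissions(counts, totals, model.freqs)
    if init is None:
        init = np.full(model.n_states, 1.0 / model.n_states)
    alpha = init * E[0]
    loglik = 0.0
    norm = alpha.sum()
    if norm == 0.0:
        return -np.inf
    loglik += np.log(norm)
    alpha /= norm
    for t in range(1, counts.size):
        gap = int(generations[t] - generations[t - 1])
        alpha = (alpha @ model.transition_power(gap)) * E[t]
        norm = alpha.sum()
        if norm == 0.0:
            return -np.inf
        loglik += np.log(norm)
        alpha /= norm
    return float(loglik)


def forward_loglik_many(
    counts: np.ndarray,
    totals: np.ndarray,
    generations: np.ndarray,
    model: WrightFisherModel,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized forward log-likelihood for many SNPs sharing the sampling grid.

    ``counts`` and ``totals`` have shape (n_snps, n_obs).  Equivalent to a
    loop of :func:`forward_loglik` but batched through matrix products, which
    is the decisive speed lever for multi-locus Ne estimation.
    """
    counts = np.asarray(counts, dtype=int)
    totals = np.asarray(totals, dtype=int)
    generations = np.asarray(generations, dtype=int)
    n_snps, n_obs = counts.shape
    freqs = model.freqs
    if init is None:
        init = np.full(model.n_states, 1.0 / model.n_states)

    E = stats.binom.pmf(counts[:, :, None], totals[:, :, None], freqs[None, None, :])
    E[totals == 0] = 1.0

    alpha = init[None, :] * E[:, 0, :]
    norm = alpha.sum(axis=1)
    loglik = np.where(norm > 0, np.log(np.where(norm > 0, norm, 1.0)), -np.inf)
    alpha = alpha / np.where(norm > 0, norm, 1.0)[:, None]
    for t in range(1, n_obs):
        gap = int(generations[t] - generations[t - 1])
        alpha = (alpha @ model.transition_power(gap)) * E[:, t, :]
        norm = alpha.sum(axis=1)
        loglik = loglik + np.where(norm > 0, np.log(np.where(norm > 0, norm, 1.0)), -np.inf)
        alpha = alpha / np.where(norm > 0, norm, 1.0)[:, None]
    return loglik


@dataclass(frozen=True)
class SnpTestResult:
    """Likelihood-ratio test of selection at one SNP."""

    s_hat: float
    loglik0: float
    loglik1: float
    lrt: float
    pvalue: float
    testable: bool = True


def test_snp(
    counts: np.ndarray,
    totals: np.ndarray,
    generations: np.ndarray,
    ne: int,
    s_grid: tuple[float, ...] = DEFAULT_S_GRID,
    n_states: int | None = None,
    refine: bool = True,
) -> SnpTestResult:
    """LRT for selection at one SNP with Ne fixed.

    The alternative log-likelihood is maximized over ``s_grid`` (which must
    contain 0) followed by golden-section refinement in the bracketing
    interval; the statistic 2*(loglik1 - loglik0) is referred to the
    chi-square(1) upper tail.
    """
    if 0.0 not in s_grid:
        raise ValueError("s_grid must contain 0")
    totals = np.asarray(totals, dtype=int)
    if totals.sum() == 0:
        return SnpTestResult(np.nan, 0.0, 0.0, np.nan, np.nan, testable=False)
    if n_states is None:
        n_states = default_n_states(ne)

    def nll(s: float) -> float:
        model = WrightFisherModel(ne=ne, s=float(s), n_states=n_states)
        return -forward_loglik(counts, totals, generations, model)

    grid = sorted(s_grid)
    vals = [nll(s) for s in grid]
    k = int(np.argmin(vals))
    loglik0 = -vals[grid.index(0.0)]
    s_best, best = grid[k], -vals[k]
    if refine:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
            )
            if -res.fun > best:
                s_best, best = float(res.x), float(-res.fun)
    lrt = max(2.0 * (best - loglik0), 0.0)
    pvalue = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SnpTestResult(s_hat=s_best, loglik0=loglik0, loglik1=best, lrt=lrt, pvalue=pvalue)


def test_snps(
    tc: TemporalCounts,
    ne: int,
    s_grid: tuple[float, ...] = DEFAULT_S_GRID,
    n_states: int | None = None,
    refine: bool = True,
) -> list[SnpTestResult]:
    """LRT at every SNP of a TemporalCounts, with batched grid evaluation.

    The grid stage evaluates every s in ``s_grid`` for all SNPs at once
    (sharing the cached transition matrices); golden-section refinement then
    runs per SNP in its bracketing interval.
    """
    if 0.0 not in s_grid:
        raise ValueError("s_grid must contain 0")
    if n_states is None:
        n_states = default_n_states(ne)
    grid = sorted(s_grid)
    testable = tc.totals.sum(axis=1) > 0
    logliks = np.full((tc.n_snps, len(grid)), -np.inf)
    for j, s in enumerate(grid):
        model = WrightFisherModel(ne=ne, s=float(s), n_states=n_states)
        logliks[:, j] = forward_loglik_many(tc.counts, tc.totals, tc.generations, model)
    zero_col = grid.index(0.0)

    results: list[SnpTestResult] = []
    for i in range(tc.n_snps):
        if not testable[i]:
            results.append(SnpTestResult(np.nan, 0.0, 0.0, np.nan, np.nan, testable=False))
            continue
        k = int(np.argmax(logliks[i]))
        loglik0 = float(logliks[i, zero_col])
        s_best, best = grid[k], float(logliks[i, k])
        if refine:
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, len(grid) - 1)]

            def nll(s: float, i=i) -> float:
                model = WrightFisherModel(ne=ne, s=float(s), n_states=n_states)
                return -forward_loglik(tc.counts[i], tc.totals[i], tc.generations, model)

            if hi > lo:
                res = optimize.minimize_scalar(
                    nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
                )
                if -res.fun > best:
                    s_best, best = float(res.x), float(-res.fun)
        lrt = max(2.0 * (best - loglik0), 0.0)
        pvalue = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
        results.append(SnpTestResult(s_best, loglik0, best, lrt, pvalue))
    return results


@dataclass(frozen=True)
class NeEstimate:
    """Profile-likelihood estimate of diploid effective population size."""

    ne_hat: float
    ci_low: float
    ci_high: float
    grid: np.ndarray
    logliks: np.ndarray
    at_boundary: bool


def estimate_ne(
    tc: TemporalCounts,
    ne_grid: np.ndarray | list[int],
    n_states: int | None = None,
) -> NeEstimate:
    """Multi-locus maximum-likelihood estimate of Ne from neutral drift.

    For each candidate Ne, sums the neutral (s = 0) forward log-likelihood
    over all loci; the point estimate refines the grid maximum with a
    parabolic fit through its neighbours, and the 95% confidence interval is
    the profile-likelihood region {Ne : loglik >= max - 1.92}, with the
    crossing points located by linear interpolation.  A maximum on the edge
    of the grid is flagged.
    """
    ne_grid = np.asarray(sorted(ne_grid), dtype=int)
    if ne_grid.size == 0:
        raise ValueError("empty Ne grid")
    if tc.n_snps < 50:
        logger.warning("estimate_ne: only %d SNPs; estimate may be unstable", tc.n_snps)
    ll = np.empty(ne_grid.size)
    for j, ne in enumerate(ne_grid):
        model = WrightFisherModel(ne=int(ne), s=0.0, n_states=n_states)
        ll[j] = forward_loglik_many(tc.counts, tc.totals, tc.generations, model).sum()
    k = int(np.argmax(ll))
    at_boundary = k in (0, ne_grid.size - 1)
    ne_hat = float(ne_grid[k])
    if not at_boundary:
        # parabolic refinement through (k-1, k, k+1)
        x = ne_grid[k - 1 : k + 2].astype(float)
        y = ll[k - 1 : k + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
        if a < 0:
            ne_hat = float(np.clip(-b / (2 * a), x[0], x[2]))

    cutoff = ll.max() - 1.92
    above = ll >= cutoff
    lo_idx = int(np.argmax(above))
    hi_idx = int(len(above) - 1 - np.argmax(above[::-1]))
    ci_low = float(ne_grid[lo_idx])
    ci_high = float(ne_grid[hi_idx])
    if lo_idx > 0:
        x0, x1 = ne_grid[lo_idx - 1], ne_grid[lo_idx]
        y0, y1 = ll[lo_idx - 1], ll[lo_idx]
        ci_low = float(x0 + (cutoff - y0) * (x1 - x0) / (y1 - y0))
    if hi_idx < ne_grid.size - 1:
        x0, x1 = ne_grid[hi_idx], ne_grid[hi_idx + 1]
        y0, y1 = ll[hi_idx], ll[hi_idx + 1]
        ci_high = float(x0 + (cutoff - y0) * (x1 - x0) / (y1 - y0))
    ci_low = min(ci_low, ne_hat)
    ci_high = max(ci_high, ne_hat)
    return NeEstimate(
        ne_hat=ne_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        grid=ne_grid,
        logliks=ll,
        at_boundary=at_boundary,
    )
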