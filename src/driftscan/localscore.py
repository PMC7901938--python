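"""Local-score aggregation of per-SNP p-values into candidate regions.

Each SNP's p-value is turned into a score X = -log10(p) - xi (xi = 1 by
default, which gives the score a negative drift under uniform p-values and
so keeps excursions finite), and the Lindley process H_i = max(0, H_{i-1} +
X_i) is run along each chromosome.  Excursions of H above a chromosome-wide
threshold — calibrated so that a whole neutral chromosome exceeds it with
probability alpha — are reported as candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


def score_transform(pvalues: np.ndarray, xi: float = 1.0) -> np.ndarray:
    """Per-SNP scores X = -log10(p) - xi; requires p in (0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log10(p) - xi


@dataclass
class ScoreTrack:
    """Scores and the running Lindley process along one chromosome."""

    chrom: str
    positions: np.ndarray
    scores: np.ndarray
    lindley: np.ndarray

    @property
    def L(self) -> int:
        return self.scores.size

    @property
    def max(self) -> float:
        return float(self.lindley.max(initial=0.0))


def lindley(scores: np.ndarray) -> np.ndarray:
    """Running Lindley process H_i = max(0, H_{i-1} + X_i), H_0 = 0."""
    x = np.asarray(scores, dtype=float)
    h = np.empty_like(x)
    acc = 0.0
    for i, xi in enumerate(x):
        acc = max(0.0, acc + xi)
        h[i] = acc
    return h


def _lindley_max_batch(x: np.ndarray) -> np.ndarray:
    """Max of the Lindley process for each row of ``x`` (vectorized over rows)."""
    h = np.zeros(x.shape[0])
    best = np.zeros(x.shape[0])
    for j in range(x.shape[1]):
        h = np.maximum(0.0, h + x[:, j])
        np.maximum(best, h, out=best)
    return best


def make_track(
    pvalues: np.ndarray, positions: np.ndarray, chrom: str = "1", xi: float = 1.0
) -> ScoreTrack:
    scores = score_transform(pvalues, xi=xi)
    return ScoreTrack(
        chrom=chrom,
        positions=np.asarray(positions, dtype=int),
        scores=scores,
        lindley=lindley(scores),
    )


def cramer_exponent(xi: float = 1.0) -> float:
    """Positive root lambda* of E[exp(lambda X)] = 1 for X = -log10(U) - xi.

    With U uniform, -log10(U) is exponential with rate ln(10), so
    E[exp(lambda X)] = exp(-lambda xi) * ln10 / (ln10 - lambda) for
    lambda < ln10.
    """
    ln10 = np.log(10.0)

    def moment(lam: float) -> float:
        return np.exp(-lam * xi) * ln10 / (ln10 - lam) - 1.0

    return float(optimize.brentq(moment, 1e-9, ln10 - 1e-9))


def cramer_prefactor(xi: float = 1.0) -> float:
    """Constant K of the tail P(max H >= a) ~ 1 - exp(-L K exp(-lambda* a)).

    Derived from the stationary upcrossing rate of the Lindley chain: the
    stationary law of H is that of the all-time maximum of the random walk,
    an atom 1 - q at zero plus an Exp(lambda*) tail with mass q = 1 -
    lambda*/ln10 (ascending ladder heights are exponential because the score's
    upper tail is), giving K = q * lambda* / (ln10 - lambda*) * 10^(-xi).
    """
    ln10 = np.log(10.0)
    lam = cramer_exponent(xi)
    q = 1.0 - lam / ln10
    return float(q * lam / (ln10 - lam) * np.exp(-ln10 * xi))


def chrom_threshold(
    L: int,
    alpha: float,
    xi: float = 1.0,
    mode: str = "mc",
    n_reps: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Chromosome-wide significance threshold for the max of the Lindley process.

    Monte-Carlo mode (default) simulates ``n_reps`` chromosomes of L i.i.d.
    uniform p-values and returns the (1 - alpha) quantile of the maximum.
    Analytic mode solves the Cramér-type tail P(max H >= a) ~ 1 - exp(-L K
    exp(-lambda* a)) for alpha, with the prefactor K of
    :func:`cramer_prefactor`; it serves as a cross-check of the Monte-Carlo
    calibration.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if mode == "analytic":
        lam = cramer_exponent(xi)
        K = cramer_prefactor(xi)
        # 1 - exp(-L K e^{-lam a}) = alpha  =>  a = -log(-log(1-alpha)/(L K))/lam
        return float(-np.log(-np.log1p(-alpha) / (L * K)) / lam)
    if mode != "mc":
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = np.empty(n_reps)
    # simulate in blocks to bound memory at ~64 MB
    block = max(1, min(n_reps, int(8e6) // max(L, 1)))
    done = 0
    while done < n_reps:
        b = min(block, n_reps - done)
        x = -np.log10(rng.random((b, L))) - xi
        maxima[done : done + b] = _lindley_max_batch(x)
        done += b
    return float(np.quantile(maxima, 1.0 - alpha))


@dataclass(frozen=True)
class SignificantRegion:
    """A significant Lindley excursion on one chromosome."""

    chrom: str
    start: int
    end: int
    n_snps: int
    peak: float
    threshold: float
    alpha: float


def call_regions(
    track: ScoreTrack, threshold: float, alpha: float = float("nan")
) -> list[SignificantRegion]:
    """Call significant regions from a score track.

    An excursion is significant when its Lindley peak reaches ``threshold``.
    Using the identity H_i = S_i - min_{k<=i} S_k (S = prefix score sums),
    the region extends from the earliest SNP achieving the peak segmental sum
    (the earliest prefix-sum minimum before the peak) to the last SNP before
    H returns to zero — the full excursion extent.  Overlapping excursion
    regions are merged.
    """
    h = track.lindley
    scores = track.scores
    L = track.L
    S = np.concatenate([[0.0], np.cumsum(scores)])
    prefix_min = np.minimum.accumulate(S)

    raw: list[tuple[int, int, float]] = []
    i = 0
    while i < L:
        if h[i] > 0.0:
            j = i
            while j + 1 < L and h[j + 1] > 0.0:
                j += 1
            k_peak = i + int(np.argmax(h[i : j + 1]))
            peak = float(h[k_peak])
            if peak >= threshold:
                # earliest k with S_k == min_{<=k_peak+1} S (widest attaining window)
                k0 = int(np.argmax(S[: k_peak + 2] <= prefix_min[k_peak + 1] + 1e-12))
                raw.append((k0, j, peak))
            i = j + 1
        else:
            i += 1

    merged: list[list] = []
    for start, end, peak in raw:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])
    return [
        SignificantRegion(
            chrom=track.chrom,
            start=int(track.positions[a]),
            end=int(track.positions[b]),
            n_snps=b - a + 1,
            peak=peak,
            threshold=float(threshold),
            alpha=alpha,
        )
        for a, b, peak in merged
    ]


def expected_false_positives(n_chromosomes: int, alpha: float) -> float:
    """Expected number of false-positive regions genome-wide.

    With a per-chromosome type-I error rate alpha, the expectation is simply
    n_chromosomes * alpha (e.g. 28 chromosomes at alpha = 0.10 give 2.8).
    """
    if n_chromosomes < 0 or alpha < 0:
        raise ValueError("inputs must be non-negative")
    return n_chromosomes * alpha


def regions_to_frame(regions: list[SignificantRegion]) -> pd.DataFrame:
    """Region table mirroring the usual report layout (lengths in kbp)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start,
                "end_bp": r.end,
                "length_kbp": (r.end - r.start) / 1000.0,
                "n_snps": r.n_snps,
                "peak": r.peak,
                "threshold": r.threshold,
                "alpha": r.alpha,
            }
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "length_kbp", "n_snps", "peak", "threshold", "alpha"],
    )


def regions_to_bed(regions: list[SignificantRegion], path: str) -> None:
    """Write regions as BED (0-based half-open; conversion happens here only)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tpeak={r.peak:.3f}\n")
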