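"""Forward-in-time Wright-Fisher simulation of temporal genotype datasets.

The simulator stands in for a livestock population genotyped over the last
few decades: diploid Wright-Fisher evolution of independent biallelic SNPs
across a handful of generations at modest effective size, with optional genic
selection, temporal sampling of a few diploids per generation, per-source
missingness with genotype-quality values, occasional ref/alt inversions
between sources, and phased haplotypes carrying an injectable partial or
complete selective sweep.

Selection is genic with a single coefficient ``s``: the post-selection
frequency is p' = p(1+s) / (1+ps), and the next generation's allele count is
Binomial(2*Ne, p').  There is no recurrent mutation (the horizon is at most
tens of generations) and no dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftscan.genodata import MISSING, GenotypeTable


def selection_update(p: np.ndarray | float, s: float) -> np.ndarray | float:
    """Deterministic one-generation frequency update under genic selection."""
    return p * (1.0 + s) / (1.0 + p * s)


@dataclass(frozen=True)
class TemporalSimConfig:
    """Configuration of a temporal genotype-dataset simulation.

    ``sampling_plan`` maps generation index (1-based) to the number of
    diploids sampled from that generation; generations absent from the plan
    are unsampled.  ``init_freq_law`` is ``("fixed", p0)``, ``("uniform", lo,
    hi)`` or ``("sfs", n_bins)`` (site-frequency-like, mass proportional to
    1/p on a discrete grid).
    """

    ne: int
    s: float
    n_generations: int
    sampling_plan: dict[int, int]
    n_snps: int
    init_freq_law: tuple = ("uniform", 0.05, 0.95)
    seed: int = 0
    start_year: int = 1980
    gen_length: int = 4

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.n_generations < 2:
            raise ValueError("need at least 2 generations")
        if any(n < 0 for n in self.sampling_plan.values()):
            raise ValueError("sample sizes must be >= 0")
        if sum(1 for n in self.sampling_plan.values() if n > 0) < 2:
            raise ValueError("at least two generations must be sampled")
        if not all(1 <= g <= self.n_generations for g in self.sampling_plan):
            raise ValueError("sampling_plan generations out of range")


@dataclass(frozen=True)
class SweepSpec:
    """An injected sweep: drive ``focal`` from ``p0`` until it reaches ``target``.

    ``max_generations`` bounds the conditioned sweep duration — attempts that
    have not reached the target in time are restarted, so the accepted sweep
    is a *recent* one whose haplotype signature has not been eroded by
    recombination.  None disables the bound.
    """

    focal: int
    s: float
    p0: float = 0.1
    target: float = 0.8
    max_generations: int | None = None


@dataclass(frozen=True)
class HaploSimConfig:
    """Configuration of a phased-haplotype simulation.

    A population of ``ne`` diploids (2*ne haplotypes) evolves by random union
    of gametes with per-adjacent-interval crossover probability
    ``recomb_prob``; founders carry standing variation at linkage equilibrium
    with per-SNP frequencies drawn uniformly.  ``n_haplotypes`` phased
    haplotypes are sampled from the final generation.
    """

    n_haplotypes: int
    n_snps: int
    positions: tuple[int, ...] | None = None
    recomb_prob: float = 0.01
    sweep: SweepSpec | None = None
    ne: int = 100
    n_generations: int = 20
    seed: int = 0
    max_restarts: int = 200

    def __post_init__(self) -> None:
        if self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be even (diploid sampling)")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise ValueError("recomb_prob must be in [0, 0.5]")
        if self.n_haplotypes > 2 * self.ne:
            raise ValueError("cannot sample more haplotypes than the population holds")
        if self.positions is not None and len(self.positions) != self.n_snps:
            raise ValueError("positions length must equal n_snps")
        if self.sweep is not None and not 0 <= self.sweep.focal < self.n_snps:
            raise ValueError("sweep focal index out of range")


class SweepFailedError(RuntimeError):
    """Raised when a conditioned sweep is lost in every allowed restart."""

    def __init__(self, restarts: int):
        super().__init__(f"sweep lost in all {restarts} restarts")
        self.restarts = restarts


def simulate_wf_trajectory(
    p0: float, ne: int, s: float, t: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Simulate a Wright-Fisher allele-frequency trajectory of length t+1.

    Each generation the allele count is drawn Binomial(2*ne, p') with
    p' = p(1+s)/(1+ps).  States 0 and 1 are absorbing.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if ne < 1:
        raise ValueError("ne must be positive")
    if t < 1:
        raise ValueError("t must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.empty(t + 1)
    freqs[0] = p = p0
    two_ne = 2 * ne
    for g in range(1, t + 1):
        p = rng.binomial(two_ne, selection_update(p, s)) / two_ne
        freqs[g] = p
    return freqs


def _simulate_trajectories(
    p0: np.ndarray, ne: int, s: float, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized trajectories for many independent SNPs; shape (t+1, n_snps)."""
    two_ne = 2 * ne
    out = np.empty((t + 1, p0.size))
    out[0] = p = np.asarray(p0, dtype=float)
    for g in range(1, t + 1):
        p = rng.binomial(two_ne, selection_update(p, s)) / two_ne
        out[g] = p
    return out


def _draw_init_freqs(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "fixed":
        return np.full(n, float(law[1]))
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        return rng.uniform(lo, hi, size=n)
    if kind == "sfs":
        n_bins = int(law[1]) if len(law) > 1 else 50
        grid = np.linspace(0.05, 0.95, n_bins)
        w = 1.0 / grid
        return rng.choice(grid, size=n, p=w / w.sum())
    raise ValueError(f"unknown init_freq_law {law!r}")


def simulate_temporal_dataset(
    cfg: TemporalSimConfig,
) -> tuple[GenotypeTable, pd.DataFrame, pd.DataFrame]:
    """Simulate a temporally sampled genotype dataset with ground truth.

    Returns (genotype table, sample metadata, ground-truth table).  Sampled
    diploid genotypes at each SNP are Binomial(2, population frequency at the
    sample's generation); birth years are assigned inside each generation's
    calendar window so generation binning recovers the simulated generation.
    The ground-truth table records s, the initial frequency and the full
    population trajectory per SNP.
    """
    rng = np.random.default_rng(cfg.seed)
    p0 = _draw_init_freqs(cfg.init_freq_law, cfg.n_snps, rng)
    traj = _simulate_trajectories(p0, cfg.ne, cfg.s, cfg.n_generations - 1, rng)

    sample_rows, geno_rows = [], []
    for gen in sorted(cfg.sampling_plan):
        n_dip = cfg.sampling_plan[gen]
        if n_dip == 0:
            continue
        freqs = traj[gen - 1]
        g = rng.binomial(2, freqs[None, :].repeat(n_dip, axis=0)).astype(np.int8)
        geno_rows.append(g)
        year0 = cfg.start_year + (gen - 1) * cfg.gen_length
        for k in range(n_dip):
            sample_rows.append(
                {
                    "sample_id": f"g{gen}_i{k}",
                    "birth_year": int(year0 + rng.integers(0, cfg.gen_length)),
                    "source": "sim",
                    "generation": gen,
                }
            )
    metadata = pd.DataFrame(sample_rows)
    genotypes = np.vstack(geno_rows)

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, cfg.n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "id": [f"snp{i}" for i in range(cfg.n_snps)],
        }
    )
    gt = GenotypeTable(
        variants=variants,
        samples=metadata[["sample_id", "source"]].copy(),
        genotypes=genotypes,
    )
    truth = pd.DataFrame(
        {
            "snp_id": variants["id"],
            "s": cfg.s,
            "p0": p0,
            "trajectory": [",".join(f"{x:.6g}" for x in traj[:, j]) for j in range(cfg.n_snps)],
        }
    )
    return gt, metadata, truth


# ---------------------------------------------------------------------------
# Haplotype simulation


def _next_generation(
    pop: np.ndarray,
    ne: int,
    recomb_prob: float,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of random union of gametes with crossovers.

    ``pop`` has shape (2*ne, m) with haplotypes 2k, 2k+1 forming individual k.
    ``fitness`` (length ne) weights the chance of each parent contributing a
    gamete.  Returns the offspring haplotype array of the same shape.
    """
    m = pop.shape[1]
    if fitness is None:
        parents = rng.integers(0, ne, size=2 * ne)
    else:
        w = fitness / fitness.sum()
        parents = rng.choice(ne, size=2 * ne, p=w)
    # each gamete: recombine the parent's two haplotypes.  Crossovers are
    # Bernoulli(recomb_prob) per interval; drawn sparsely (count then
    # positions without replacement) since counts are tiny at realistic rates
    h0 = pop[2 * parents]
    h1 = pop[2 * parents + 1]
    flips = np.zeros((2 * ne, m), dtype=np.int8)
    flips[:, 0] = rng.integers(0, 2, size=2 * ne)
    if m > 1 and recomb_prob > 0.0:
        k = rng.binomial(m - 1, recomb_prob, size=2 * ne)
        singles = np.flatnonzero(k == 1)
        flips[singles, rng.integers(1, m, size=singles.size)] += 1
        for row in np.flatnonzero(k >= 2):
            flips[row, 1 + rng.choice(m - 1, size=k[row], replace=False)] += 1
    chooser = np.cumsum(flips, axis=1, dtype=np.int8) & 1
    return np.where(chooser == 0, h0, h1).astype(np.int8)


def simulate_haplotypes(cfg: HaploSimConfig) -> "HaplotypeTable":
    """Simulate phased haplotypes, optionally conditioned on a partial sweep.

    Founders carry standing variation at linkage equilibrium.  If a sweep is
    configured, the focal allele starts at frequency ``p0`` with every copy
    placed on one shared founder background — the defining haplotype
    structure of a hard sweep, whose early stochastic phase is not simulated
    — and the simulation runs until the focal frequency reaches ``target``
    (restarting on loss, up to ``max_restarts``); otherwise the population
    evolves neutrally for ``n_generations``.
    """
    from driftscan.nsl import HaplotypeTable

    rng = np.random.default_rng(cfg.seed)
    positions = (
        np.asarray(cfg.positions, dtype=int)
        if cfg.positions is not None
        else np.arange(1, cfg.n_snps + 1) * 1000
    )
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")

    n_pop = 2 * cfg.ne
    sweep = cfg.sweep
    for restart in range(cfg.max_restarts):
        init_freq = rng.uniform(0.05, 0.95, size=cfg.n_snps)
        if sweep is not None:
            init_freq[sweep.focal] = 0.0
        pop = (rng.random((n_pop, cfg.n_snps)) < init_freq[None, :]).astype(np.int8)
        if sweep is not None:
            # all sweep copies share one ancestral background haplotype
            n_copies = max(1, int(round(sweep.p0 * n_pop)))
            carriers = rng.choice(n_pop, size=n_copies, replace=False)
            pop[carriers] = pop[carriers[0]]
            pop[carriers, sweep.focal] = 1
        ok = True
        if sweep is None:
            for _ in range(cfg.n_generations):
                pop = _next_generation(pop, cfg.ne, cfg.recomb_prob, rng)
        else:
            horizon = sweep.max_generations if sweep.max_generations else 20 * cfg.ne
            for _ in range(horizon):  # loss or overrun triggers restart
                geno = pop[0::2, sweep.focal] + pop[1::2, sweep.focal]
                fitness = (1.0 + sweep.s) ** geno.astype(float)
                pop = _next_generation(pop, cfg.ne, cfg.recomb_prob, rng, fitness=fitness)
                f = pop[:, sweep.focal].mean()
                if f >= sweep.target:
                    break
                if f == 0.0:
                    ok = False
                    break
            else:
                ok = False
        if ok:
            # draw the sample; with a sweep, condition the sampled focal
            # frequency into the target band (the stopping rule applies to
            # the output panel, not just the population)
            for _ in range(50):
                idx = rng.choice(cfg.ne, size=cfg.n_haplotypes // 2, replace=False)
                hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).reshape(-1)
                if sweep is None:
                    break
                f_sample = pop[hap_idx, sweep.focal].mean()
                if abs(f_sample - sweep.target) <= 0.05:
                    break
            else:
                continue  # population drifted past the band; restart
            return HaplotypeTable(
                haplotypes=pop[hap_idx].copy(), positions=positions, chrom="1"
            )
    raise SweepFailedError(cfg.max_restarts)


# ---------------------------------------------------------------------------
# Dataset corruption: missingness with GQ, allele flips


def inject_missingness(
    gt: GenotypeTable,
    rate: float,
    gq_law: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Set a random fraction ``rate`` of genotypes missing and attach GQ values.

    Remaining genotypes receive GQ drawn from ``gq_law``: high-quality calls
    uniform on [hi_lo, hi_hi] (default 20-60) with a fraction ``low_frac``
    (default 0.02) drawn uniform on [0, 9] to exercise the GQ<10 mask.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    law = {"hi_lo": 20.0, "hi_hi": 60.0, "low_frac": 0.02, **(gq_law or {})}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = gt.copy()
    if rate == 0.0 and gt.gq is not None:
        return out
    miss = rng.random(out.genotypes.shape) < rate
    out.genotypes[miss] = MISSING
    gq = rng.uniform(law["hi_lo"], law["hi_hi"], size=out.genotypes.shape)
    low = rng.random(out.genotypes.shape) < law["low_frac"]
    gq[low] = rng.uniform(0.0, 9.0, size=int(low.sum()))
    gq = np.round(gq)
    gq[out.genotypes == MISSING] = np.nan
    out.gq = gq
    return out


def inject_allele_flip(
    gt: GenotypeTable, snp_indices: np.ndarray | list[int], source_label: str
) -> GenotypeTable:
    """Recode g -> 2-g at the listed SNPs for samples of one source.

    Emulates a ref/alt inversion introduced while merging datasets; applying
    the same flip twice restores the original table.
    """
    out = gt.copy()
    idx = np.asarray(snp_indices, dtype=int)
    rows = (out.samples["source"] == source_label).to_numpy()
    if not rows.any():
        raise ValueError(f"no samples with source {source_label!r}")
    sub = out.genotypes[np.ix_(rows, idx)]
    obs = sub != MISSING
    sub[obs] = 2 - sub[obs]
    out.genotypes[np.ix_(rows, idx)] = sub
    return out


# ---------------------------------------------------------------------------
# Ground-truth I/O


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
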