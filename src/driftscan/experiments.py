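"""Calibration and power experiments for the temporal and haplotype scans.

Self-contained validation studies run on synthetic data from
:mod:`driftscan.syndata`: type-I calibration of the Wright-Fisher HMM test,
the genome-wide false-positive budget of the local-score caller, confidence
-interval coverage of the Ne estimator, selection-coefficient sign recovery,
and sweep-detection power of the standardized nSL scan.  Problem sizes
default to desk scale; every experiment is driven by one seed.
"""

from __future__ import annotations

import numpy as np

from driftscan import localscore, nsl, syndata, temporal, wfhmm


def simulate_neutral_counts(
    ne: int,
    n_snps: int,
    n_generations: int,
    n_per_gen: int,
    rng: np.random.Generator,
    init_freq_law: tuple = ("uniform", 0.1, 0.9),
) -> temporal.TemporalCounts:
    """Neutral temporal allele counts straight from the Wright-Fisher law."""
    cfg = syndata.TemporalSimConfig(
        ne=ne, s=0.0, n_generations=n_generations,
        sampling_plan={g: n_per_gen for g in range(1, n_generations + 1)},
        n_snps=n_snps, init_freq_law=init_freq_law,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    gt, md, _ = syndata.simulate_temporal_dataset(cfg)
    return temporal.build_temporal_counts(gt, md["generation"].to_numpy())


def hmm_type1_calibration(
    seed: int,
    n_snps: int = 500,
    ne: int = 100,
    n_generations: int = 8,
    n_per_gen: int = 20,
    maf_min: float = 0.05,
) -> dict:
    """Fraction of neutral-simulation LRT p-values below 0.05 (target ~0.05),
    plus the Kolmogorov-Smirnov distance of the p-values from uniformity."""
    from scipy import stats

    rng = np.random.default_rng([seed, 101])
    tc = simulate_neutral_counts(ne, n_snps, n_generations, n_per_gen, rng)
    tc = temporal.maf_filter_temporal(tc, maf_min=maf_min)
    results = wfhmm.test_snps(tc, ne=ne)
    pvals = np.array([r.pvalue for r in results if r.testable])
    ks = stats.kstest(pvals, "uniform").statistic
    return {
        "n_tested": pvals.size,
        "frac_below_05": float((pvals < 0.05).mean()),
        "ks_uniform": float(ks),
        "pvalues": pvals,
    }


def null_genome_region_count(
    seed: int,
    n_runs: int = 200,
    n_chromosomes: int = 28,
    L: int = 1000,
    alpha: float = 0.10,
    threshold_reps: int = 2000,
) -> dict:
    """Mean number of local-score regions called on fully neutral genomes.

    Simulates ``n_runs`` genomes of ``n_chromosomes`` chromosomes of L i.i.d.
    uniform p-values each, calls regions at the per-chromosome Monte-Carlo
    threshold, and reports the mean genome-wide region count (expectation
    n_chromosomes * alpha) and the per-chromosome hit rate (expectation
    alpha).
    """
    rng = np.random.default_rng([seed, 202])
    thr = localscore.chrom_threshold(L, alpha, n_reps=threshold_reps, seed=rng)
    positions = np.arange(1, L + 1) * 1000
    counts = np.zeros(n_runs)
    chrom_hits = 0
    for run in range(n_runs):
        for c in range(n_chromosomes):
            track = localscore.make_track(rng.random(L), positions, chrom=str(c + 1))
            regions = localscore.call_regions(track, thr, alpha)
            counts[run] += len(regions)
            chrom_hits += bool(regions)
    return {
        "threshold": float(thr),
        "mean_regions_per_genome": float(counts.mean()),
        "expected": localscore.expected_false_positives(n_chromosomes, alpha),
        "chrom_hit_rate": chrom_hits / (n_runs * n_chromosomes),
    }


def ne_ci_coverage(
    seed: int,
    true_ne: int = 200,
    n_replicates: int = 50,
    n_snps: int = 500,
    n_generations: int = 8,
    n_per_gen: int = 30,
    ne_grid: tuple = tuple(range(100, 351, 25)),
) -> dict:
    """Coverage of the 95% profile-likelihood CI for Ne over replicates."""
    rng = np.random.default_rng([seed, 303])
    covered = 0
    ne_hats = []
    for _ in range(n_replicates):
        tc = simulate_neutral_counts(true_ne, n_snps, n_generations, n_per_gen, rng)
        est = wfhmm.estimate_ne(tc, ne_grid)
        covered += est.ci_low <= true_ne <= est.ci_high
        ne_hats.append(est.ne_hat)
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "median_ne_hat": float(np.median(ne_hats)),
    }


def s_sign_recovery(
    seed: int,
    true_s: float = 0.5,
    n_replicates: int = 200,
    ne: int = 100,
    n_generations: int = 8,
    n_per_gen: int = 50,
    p0: float = 0.2,
) -> dict:
    """Median estimated selection coefficient across selected-SNP replicates."""
    rng = np.random.default_rng([seed, 404])
    counts = np.empty((n_replicates, n_generations), dtype=int)
    totals = np.full((n_replicates, n_generations), 2 * n_per_gen, dtype=int)
    for i in range(n_replicates):
        traj = syndata.simulate_wf_trajectory(p0, ne, true_s, n_generations - 1, seed=rng)
        counts[i] = rng.binomial(2 * n_per_gen, traj)
    tc = temporal.TemporalCounts(
        snp_ids=np.array([f"rep{i}" for i in range(n_replicates)]),
        generations=np.arange(1, n_generations + 1),
        counts=counts, totals=totals,
    )
    results = wfhmm.test_snps(tc, ne=ne)
    s_hats = np.array([r.s_hat for r in results])
    return {
        "median_s_hat": float(np.median(s_hats)),
        "frac_positive": float((s_hats > 0).mean()),
        "n_replicates": n_replicates,
    }


def nsl_sweep_power(
    seed: int,
    n_replicates: int = 50,
    n_haplotypes: int = 40,
    n_snps: int = 2000,
    sweep_s: float = 0.1,
    target: float = 0.8,
    ne: int = 2000,
    recomb_prob: float = 2e-3,
    sweep_p0: float = 0.04,
    sweep_max_generations: int = 60,
    top_quantile: float = 0.01,
) -> dict:
    """Fraction of injected-sweep replicates placing the focal SNP's
    standardized nSL in the chromosome's top quantile.

    The defaults describe a recent hard sweep on a chip-density marker
    panel: adjacent-SNP recombination 2e-3 (~0.2 cM spacing), a population
    large enough (Ne = 2,000) that background diversity is not consumed by
    drift on the sweep's timescale, and a sweep conditioned to reach the
    target within 60 generations so its haplotype footprint is recent.
    """
    rng = np.random.default_rng([seed, 505])
    focal = n_snps // 2
    hits = 0
    used = 0
    for _ in range(n_replicates):
        cfg = syndata.HaploSimConfig(
            n_haplotypes=n_haplotypes, n_snps=n_snps, recomb_prob=recomb_prob,
            ne=ne, seed=int(rng.integers(0, 2**31 - 1)),
            sweep=syndata.SweepSpec(
                focal=focal, s=sweep_s, p0=sweep_p0, target=target,
                max_generations=sweep_max_generations,
            ),
        )
        table = syndata.simulate_haplotypes(cfg)
        records = [nsl.orient_positive(r) for r in nsl.compute_nsl(table)]
        records = nsl.standardize_bins(records)
        z = np.array([r.std_score if r.defined else -np.inf for r in records])
        if not np.isfinite(z[focal]):
            continue
        used += 1
        cut = np.quantile(z[np.isfinite(z)], 1.0 - top_quantile)
        hits += z[focal] >= cut
    return {
        "power": hits / used if used else float("nan"),
        "n_used": used,
        "n_replicates": n_replicates,
    }
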