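#!/usr/bin/env python
"""Simulate the study's raw material: three genotyping "sources" sampled over
eight generations of a Wright-Fisher population, plus phased haplotypes
carrying one injected partial sweep.

Writes per-source VCFs (with GQ for the WGS-like source), a sample-metadata
TSV, the per-SNP ground truth, and the phased haplotype panel under
results/data/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from driftscan import genodata, syndata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=str, default="results/data")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    # temporal dataset: Ne=400 (the scale of a managed beef breed), 8
    # generations, mostly neutral SNPs plus a handful under strong selection
    cfg_neutral = syndata.TemporalSimConfig(
        ne=400, s=0.0, n_generations=8,
        sampling_plan={g: 14 for g in range(1, 9)},
        n_snps=450, seed=int(rng.integers(2**31)),
    )
    cfg_selected = syndata.TemporalSimConfig(
        ne=400, s=0.5, n_generations=8,
        sampling_plan={g: 14 for g in range(1, 9)},
        n_snps=6, seed=int(rng.integers(2**31)),
        init_freq_law=("fixed", 0.15),
    )
    gt_n, md, truth_n = syndata.simulate_temporal_dataset(cfg_neutral)
    gt_s, _, truth_s = syndata.simulate_temporal_dataset(cfg_selected)
    # place the selected SNPs on their own stretch of the chromosome
    gt_s.variants["pos"] += 10_000_000
    gt_s.variants["id"] = [f"sel{i}" for i in range(gt_s.n_snps)]
    truth_s = truth_s.assign(snp_id=gt_s.variants["id"].to_numpy())
    gt = genodata.GenotypeTable(
        variants=pd.concat([gt_n.variants, gt_s.variants], ignore_index=True),
        samples=gt_n.samples,
        genotypes=np.hstack([gt_n.genotypes, gt_s.genotypes]),
    )
    truth = pd.concat([truth_n, truth_s], ignore_index=True)

    # split samples into three sources with source-specific missingness
    n = gt.n_samples
    thirds = np.array_split(rng.permutation(n), 3)
    specs = [
        ("chip50k", 0.01, {"low_frac": 0.005}),
        ("chip770k", 0.01, {"low_frac": 0.005}),
        ("wgs", 0.25, {"low_frac": 0.02}),
    ]
    md = md[["sample_id", "birth_year", "source"]].copy()
    for rows, (label, miss, gq_law) in zip(thirds, specs):
        sub = genodata.GenotypeTable(
            variants=gt.variants,
            samples=gt.samples.iloc[rows].assign(source=label),
            genotypes=gt.genotypes[rows],
        )
        sub = syndata.inject_missingness(sub, miss, gq_law=gq_law,
                                         seed=int(rng.integers(2**31)))
        genodata.write_vcf(sub, str(out / f"{label}.vcf"))
        md.loc[md["sample_id"].isin(sub.samples["sample_id"]), "source"] = label
        print(f"{label}: {sub.n_samples} samples, {sub.n_snps} SNPs, "
              f"{(sub.genotypes == genodata.MISSING).mean():.1%} missing")
    genodata.write_metadata(md, str(out / "metadata.tsv"))
    syndata.write_truth(truth, str(out / "truth.tsv"))

    # phased haplotypes with one partial hard sweep for the nSL scan
    hap_cfg = syndata.HaploSimConfig(
        n_haplotypes=40, n_snps=2000, recomb_prob=2e-3, ne=2000,
        seed=int(rng.integers(2**31)),
        sweep=syndata.SweepSpec(focal=1000, s=0.1, p0=0.04, target=0.8,
                                max_generations=60),
    )
    table = syndata.simulate_haplotypes(hap_cfg)
    np.savetxt(out / "haplotypes.tsv", table.haplotypes, fmt="%d", delimiter="\t")
    np.savetxt(out / "hap_positions.tsv", table.positions, fmt="%d")
    print(f"haplotypes: {table.n_haplotypes} x {table.n_snps}, "
          f"sweep focal frequency {table.haplotypes[:, 1000].mean():.2f}")


if __name__ == "__main__":
    main()
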