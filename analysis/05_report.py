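#!/usr/bin/env python
"""Joint report: allele-frequency trajectories of each test's top SNPs and
the rank correlation between the two scans.

Reads the scan outputs of 03_scan_temporal.py and 04_scan_nsl.py plus the
temporal counts of 02_preprocess.py, exports per-generation observed
frequencies for the top-5 SNPs of each test, and summarizes how little the
two signals correlate (they target different timescales of selection).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from driftscan import pipeline
from driftscan.temporal import TemporalCounts


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=str, default="results")
    ap.add_argument("--k", type=int, default=5)
    args = ap.parse_args()
    res = Path(args.results)

    scan = pd.read_csv(res / "hmm_scan.tsv", sep="\t")
    counts_long = pd.read_csv(res / "temporal_counts.tsv", sep="\t")
    wide_c = counts_long.pivot(index="snp_id", columns="generation", values="count")
    wide_t = counts_long.pivot(index="snp_id", columns="generation", values="total")
    tc = TemporalCounts(
        snp_ids=wide_c.index.to_numpy(),
        generations=wide_c.columns.to_numpy(),
        counts=wide_c.to_numpy(),
        totals=wide_t.to_numpy(),
    )

    nsl_rec = None
    nsl_path = res / "nsl_scan.tsv"
    if nsl_path.exists():
        nsl_rec = pd.read_csv(nsl_path, sep="\t")
        # the haplotype panel is a separate simulated chromosome, so the two
        # scans share no SNP ids; the correlation summary applies only when
        # both tests ran on the same SNPs
        nsl_rec = nsl_rec.assign(snp_id=[f"hap{p}" for p in nsl_rec["pos"]])

    table, summary = pipeline.report_trajectories(scan, nsl_rec, tc, k=args.k)
    table.to_csv(res / "top_snp_trajectories.tsv", sep="\t", index=False)
    print(f"exported trajectories for {table['snp_id'].nunique()} SNPs")
    for sid, sub in table.groupby("snp_id"):
        series = " -> ".join(f"{f:.2f}" for f in sub.sort_values("generation")["frequency"])
        print(f"  {sid}: {series}")
    if summary:
        print(f"HMM vs nSL Spearman rho: {summary['spearman_rho']:.3f} "
              f"over {summary['n_shared_snps']} shared SNPs")
    else:
        print("HMM vs nSL rank correlation: no shared SNPs between the two scans")


if __name__ == "__main__":
    main()
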