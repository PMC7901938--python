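#!/usr/bin/env python
"""Clean and merge the three simulated sources and build temporal counts.

Reads the VCFs written by 01_simulate.py, masks low-GQ genotypes, applies the
per-source missingness filters (40% for the WGS-like source, 5% for chips),
merges on position with ref/alt reconciliation, removes inbred/related
animals per generation via the GRM, and writes the generation-binned allele
counts under results/.
"""

import argparse
from pathlib import Path

from driftscan import genodata, pipeline, temporal
from driftscan.pipeline import PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    tables = [
        genodata.read_vcf(str(data / f"{label}.vcf"), source=label)
        for label in ("chip50k", "chip770k", "wgs")
    ]
    metadata = genodata.read_metadata(str(data / "metadata.tsv"))
    config = PipelineConfig(seed=42)

    merged, md, attrition = pipeline.preprocess(
        tables, metadata, config, wgs_sources=("wgs",)
    )
    print("attrition:", attrition)

    plan = temporal.GenerationPlan(config.start_year, config.gen_length)
    filtered, md2 = temporal.relatedness_filter_dataset(merged, md, plan)
    print(f"samples after relatedness filter: {filtered.n_samples}/{merged.n_samples}")

    labels = md2.set_index("sample_id").loc[
        filtered.samples["sample_id"], "generation"
    ].to_numpy()
    tc = temporal.build_temporal_counts(filtered, labels)
    tc = temporal.maf_filter_temporal(tc, maf_min=config.scan_maf_min)
    print(f"SNPs after MAF filter: {tc.n_snps}")
    tc.to_frame().to_csv(out / "temporal_counts.tsv", sep="\t", index=False)
    md2.to_csv(out / "samples_retained.tsv", sep="\t", index=False)
    sizes = md2.groupby("generation").size().rename("n_samples").reset_index()
    sizes.to_csv(out / "generation_sizes.tsv", sep="\t", index=False)
    print(sizes.to_string(index=False))


if __name__ == "__main__":
    main()
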