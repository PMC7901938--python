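"""End-to-end pipelines: clean/merge -> temporal counts -> HMM scan -> regions,
and the phased-haplotype nSL scan, plus joint reporting.

Each run is driven by a single :class:`PipelineConfig` (loadable from YAML);
all randomness flows from one root seed through named per-stage substreams,
and every stage logs its record counts so dataset attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from driftscan import genodata, localscore, nsl, temporal, wfhmm

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and grids of the scan pipelines, with study defaults."""

    # generation plan
    start_year: int = 1980
    gen_length: int = 4
    # cleaning thresholds
    gq_min: float = 10.0
    max_missing_wgs: float = 0.40
    max_missing_chip: float = 0.05
    inb_max: float = 0.07
    rel_max: float = 0.1
    grm_maf_min: float = 0.10
    scan_maf_min: float = 0.05
    discordance_eps: float = 0.05
    # HMM scan
    ne_grid: tuple = tuple(range(50, 801, 50))
    s_grid: tuple = wfhmm.DEFAULT_S_GRID
    # local score
    alphas: tuple = (0.01, 0.05, 0.10)
    xi: float = 1.0
    threshold_mode: str = "mc"
    threshold_reps: int = 2000
    # nSL
    nsl_bins: int = 20
    nsl_threshold: float = 5.0
    nsl_strong_threshold: float = 6.0
    nsl_gap_bp: int = 1_000_000
    nsl_region_min_snps: int = 1
    nsl_strong_min_snps: int = 10
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ne_grid", "s_grid", "alphas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def substream(self, stage: str) -> np.random.Generator:
        """Named, reproducible RNG substream derived from the root seed."""
        return np.random.default_rng([self.seed, int.from_bytes(stage.encode(), "big") % (2**31)])


@dataclass
class TemporalScanResult:
    scan: pd.DataFrame
    regions: pd.DataFrame
    ne_estimate: wfhmm.NeEstimate
    counts: temporal.TemporalCounts
    attrition: dict


def preprocess(
    tables: list[genodata.GenotypeTable],
    metadata: pd.DataFrame,
    config: PipelineConfig,
    wgs_sources: tuple[str, ...] = (),
) -> tuple[genodata.GenotypeTable, pd.DataFrame, dict]:
    """Clean and merge per-source tables: GQ mask, missingness filter, merge.

    WGS-like sources get the lenient missingness threshold (default 40%),
    chip-like sources the strict one (5%).  Returns the merged table, the
    metadata restricted to its samples, and an attrition log.
    """
    attrition = {}
    cleaned = []
    for t in tables:
        src = t.samples["source"].iloc[0]
        t2 = genodata.mask_low_gq(t, threshold=config.gq_min)
        lim = config.max_missing_wgs if src in wgs_sources else config.max_missing_chip
        t3 = genodata.filter_missingness(t2, lim)
        attrition[f"{src}_snps_in"] = t.n_snps
        attrition[f"{src}_snps_kept"] = t3.n_snps
        cleaned.append(t3)
    merged = cleaned[0] if len(cleaned) == 1 else genodata.merge_sources(cleaned)
    attrition["merged_snps"] = merged.n_snps
    attrition["merged_samples"] = merged.n_samples
    md = metadata[metadata["sample_id"].isin(merged.samples["sample_id"])].reset_index(drop=True)
    return merged, md, attrition


def run_scan_temporal(
    tables: list[genodata.GenotypeTable],
    metadata: pd.DataFrame,
    config: PipelineConfig,
    wgs_sources: tuple[str, ...] = (),
    ne_fixed: int | None = None,
    out_dir: str | Path | None = None,
) -> TemporalScanResult:
    """Full temporal scan: preprocess -> filters -> Ne -> LRT -> local score.

    Discordance-flagged SNPs are excluded from testing.  When ``ne_fixed`` is
    given the Ne-estimation stage is skipped (the estimate is still returned
    as a degenerate object).  Writes TSV/BED outputs when ``out_dir`` is set.
    """
    merged, md, attrition = preprocess(tables, metadata, config, wgs_sources)

    flags = genodata.flag_discordant_snps(merged, eps=config.discordance_eps)
    if flags and merged.samples["source"].nunique() > 1:
        bad = np.asarray([f.snp_index for f in flags], dtype=int)
        keep = np.setdiff1d(np.arange(merged.n_snps), bad)
        merged = merged.take_variants(keep)
    attrition["discordant_flagged"] = len(flags)

    plan = temporal.GenerationPlan(config.start_year, config.gen_length)
    filtered, md2 = temporal.relatedness_filter_dataset(
        merged, md, plan,
        inb_max=config.inb_max, rel_max=config.rel_max, grm_maf_min=config.grm_maf_min,
    )
    attrition["samples_after_relatedness"] = filtered.n_samples

    order = {sid: g for sid, g in zip(md2["sample_id"], md2["generation"])}
    labels = np.asarray([order[sid] for sid in filtered.samples["sample_id"]])
    tc = temporal.build_temporal_counts(filtered, labels)
    tc = temporal.maf_filter_temporal(tc, maf_min=config.scan_maf_min)
    attrition["snps_after_maf"] = tc.n_snps
    if tc.n_snps == 0:
        raise RuntimeError(f"no SNP survived filtering; attrition: {attrition}")

    if ne_fixed is None:
        ne_est = wfhmm.estimate_ne(tc, config.ne_grid)
        ne_used = int(round(ne_est.ne_hat))
    else:
        ne_used = int(ne_fixed)
        ne_est = wfhmm.NeEstimate(
            ne_hat=float(ne_fixed), ci_low=float(ne_fixed), ci_high=float(ne_fixed),
            grid=np.asarray([ne_fixed]), logliks=np.asarray([0.0]), at_boundary=False,
        )
    attrition["ne_used"] = ne_used

    results = wfhmm.test_snps(tc, ne=ne_used, s_grid=config.s_grid)
    scan = pd.DataFrame(
        {
            "snp_id": tc.snp_ids,
            "chrom": tc.variants["chrom"].to_numpy() if tc.variants is not None else "1",
            "pos": tc.variants["pos"].to_numpy() if tc.variants is not None else 0,
            "s_hat": [r.s_hat for r in results],
            "lrt": [r.lrt for r in results],
            "pvalue": [r.pvalue for r in results],
            "testable": [r.testable for r in results],
        }
    )

    rng = config.substream("localscore")
    region_frames = []
    thresholds_log = []
    testable = scan[scan["testable"]]
    for chrom, sub in testable.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        track = localscore.make_track(
            sub["pvalue"].to_numpy(), sub["pos"].to_numpy(), chrom=str(chrom), xi=config.xi
        )
        for alpha in config.alphas:
            thr = localscore.chrom_threshold(
                track.L, alpha, xi=config.xi,
                mode=config.threshold_mode, n_reps=config.threshold_reps, seed=rng,
            )
            thresholds_log.append({"chrom": chrom, "alpha": alpha, "L": track.L, "threshold": thr})
            region_frames.append(localscore.regions_to_frame(localscore.call_regions(track, thr, alpha)))
    regions = (
        pd.concat(region_frames, ignore_index=True)
        if region_frames
        else localscore.regions_to_frame([])
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scan.to_csv(out / "hmm_scan.tsv", sep="\t", index=False)
        regions.to_csv(out / "hmm_regions.tsv", sep="\t", index=False)
        pd.DataFrame(thresholds_log).to_csv(out / "thresholds.tsv", sep="\t", index=False)
        _write_run_metadata(out / "scan_temporal_meta.json", config, attrition)
    return TemporalScanResult(scan=scan, regions=regions, ne_estimate=ne_est, counts=tc, attrition=attrition)


def merge_variant_scans(primary: pd.DataFrame, secondary: pd.DataFrame) -> pd.DataFrame:
    """Join two dataset-variant scans, preferring the larger-sample run.

    For SNPs tested in both variants the ``primary`` (larger-sample, e.g.
    with-WGS) p-value is kept; SNPs only in ``secondary`` are appended.
    """
    extra = secondary[~secondary["snp_id"].isin(primary["snp_id"])]
    return pd.concat([primary, extra], ignore_index=True)


@dataclass
class NslScanResult:
    records: pd.DataFrame
    regions: pd.DataFrame
    attrition: dict


def run_scan_nsl(
    table: nsl.HaplotypeTable,
    config: PipelineConfig,
    imputed_counts: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> NslScanResult:
    """nSL scan on phased haplotypes: raw -> orient -> bin-standardize -> regions."""
    records = nsl.compute_nsl(table)
    records = [nsl.orient_positive(r) for r in records]
    records = nsl.standardize_bins(records, n_bins=config.nsl_bins)
    attrition = {
        "snps_total": table.n_snps,
        "snps_defined": sum(1 for r in records if r.defined),
    }
    regions = nsl.call_candidates(
        records,
        table.positions,
        chrom=table.chrom,
        snp_threshold=config.nsl_threshold,
        gap_bp=config.nsl_gap_bp,
        region_min_snps=config.nsl_region_min_snps,
        strong_threshold=config.nsl_strong_threshold,
        strong_min_snps=config.nsl_strong_min_snps,
    )
    rec_frame = nsl.records_to_frame(records, table.positions, chrom=table.chrom)
    reg_frame = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "n_candidate_snps": r.n_candidate_snps, "n_strong_snps": r.n_strong_snps,
                "max_std_nsl": r.max_std_score, "tier": r.tier,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_candidate_snps", "n_strong_snps", "max_std_nsl", "tier"],
    )
    if imputed_counts is not None and regions:
        bias = nsl.imputation_bias_check(
            regions, table.positions, imputed_counts, seed=config.substream("nsl-bias")
        )
        reg_frame = reg_frame.merge(
            bias[["chrom", "start", "end", "mean_imputed", "pvalue"]],
            on=["chrom", "start", "end"], how="left",
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rec_frame.to_csv(out / "nsl_scan.tsv", sep="\t", index=False)
        reg_frame.to_csv(out / "nsl_regions.tsv", sep="\t", index=False)
        _write_run_metadata(out / "scan_nsl_meta.json", config, attrition)
    return NslScanResult(records=rec_frame, regions=reg_frame, attrition=attrition)


def report_trajectories(
    scan: pd.DataFrame,
    nsl_records: pd.DataFrame | None,
    counts: temporal.TemporalCounts,
    k: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Observed allele-frequency trajectories of each test's top-k SNPs.

    Returns a long table (test, snp_id, generation, frequency) built directly
    from counts/totals, plus a summary with the Spearman rank correlation
    between the two tests' statistics over shared SNPs.
    """
    from scipy import stats as sps

    rows = []
    idx_of = {sid: i for i, sid in enumerate(counts.snp_ids)}

    def add(test: str, snp_ids) -> None:
        for sid in snp_ids:
            if sid not in idx_of:
                continue
            i = idx_of[sid]
            for j, g in enumerate(counts.generations):
                tot = counts.totals[i, j]
                rows.append(
                    {
                        "test": test,
                        "snp_id": sid,
                        "generation": int(g),
                        "frequency": counts.counts[i, j] / tot if tot else np.nan,
                        "total": int(tot),
                    }
                )

    if k > 0:
        top_hmm = scan.nsmallest(k, "pvalue")["snp_id"]
        add("hmm", top_hmm)
        if nsl_records is not None and "std_nsl" in nsl_records:
            top_nsl = nsl_records.nlargest(k, "std_nsl")
            if "snp_id" in top_nsl:
                add("nsl", top_nsl["snp_id"])

    summary: dict = {}
    if nsl_records is not None and "snp_id" in nsl_records.columns:
        joined = scan.merge(nsl_records[["snp_id", "std_nsl"]], on="snp_id")
        joined = joined.dropna(subset=["lrt", "std_nsl"])
        if len(joined) >= 3:
            rho, _ = sps.spearmanr(joined["lrt"], joined["std_nsl"])
            summary["spearman_rho"] = float(rho)
            summary["n_shared_snps"] = int(len(joined))
    return pd.DataFrame(rows, columns=["test", "snp_id", "generation", "frequency", "total"]), summary


def _write_run_metadata(path: Path, config: PipelineConfig, attrition: dict) -> None:
    import driftscan

    meta = {
        "driftscan_version": driftscan.__version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "attrition": attrition,
    }
    path.write_text(json.dumps(meta, indent=2, default=str))
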