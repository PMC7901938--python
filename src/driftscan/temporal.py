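"""Generation binning, relatedness filtering and temporal allele counts.

Dated samples are binned into non-overlapping calendar periods of fixed
length (the generation time, 4 years by default), inbred and closely related
animals are removed per generation using a genomic relationship matrix so the
data better satisfy Wright-Fisher assumptions, and per-SNP allele counts are
assembled per generation for the time-series test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from driftscan.genodata import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationPlan:
    """Tiling of calendar years into generations.

    Generation g (1-based) covers years
    [start_year + (g-1)*gen_length, start_year + g*gen_length - 1].
    """

    start_year: int
    gen_length: int = 4

    def __post_init__(self) -> None:
        if self.gen_length < 1:
            raise ValueError("gen_length must be >= 1")

    def n_generations(self, max_year: int) -> int:
        """Number of periods needed to cover years up to ``max_year``."""
        return (max_year - self.start_year) // self.gen_length + 1


def assign_generations(birth_years: np.ndarray | list[int], plan: GenerationPlan) -> np.ndarray:
    """Map birth years to 1-based generation labels under ``plan``."""
    years = np.asarray(birth_years, dtype=int)
    if np.any(years < plan.start_year):
        raise ValueError("birth year before plan start_year")
    return (years - plan.start_year) // plan.gen_length + 1


@dataclass
class TemporalCounts:
    """Per-SNP alt-allele counts per sampled generation.

    ``counts`` and ``totals`` have shape (n_snps, n_generations); ``totals``
    is twice the number of non-missing diploid genotypes.  ``generations``
    holds the (strictly increasing) generation indices, so gaps between
    consecutive sampled generations are visible to the HMM.
    """

    snp_ids: np.ndarray
    generations: np.ndarray
    counts: np.ndarray
    totals: np.ndarray
    variants: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.totals = np.asarray(self.totals, dtype=int)
        if self.counts.shape != self.totals.shape:
            raise ValueError("counts/totals shape mismatch")
        if np.any(self.counts > self.totals) or np.any(self.counts < 0):
            raise ValueError("need 0 <= count <= total")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return self.counts.shape[0]

    def pooled_frequency(self) -> np.ndarray:
        """Alt frequency pooled over all sampling times."""
        tot = self.totals.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts.sum(axis=1) / tot

    def take(self, idx: np.ndarray) -> "TemporalCounts":
        return TemporalCounts(
            snp_ids=self.snp_ids[idx],
            generations=self.generations,
            counts=self.counts[idx],
            totals=self.totals[idx],
            variants=None if self.variants is None else self.variants.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.snp_ids):
            for j, g in enumerate(self.generations):
                rows.append((sid, int(g), int(self.counts[i, j]), int(self.totals[i, j])))
        return pd.DataFrame(rows, columns=["snp_id", "generation", "count", "total"])


@dataclass
class RelatednessMatrix:
    """GRM over the samples of one generation: diagonal = 1 + inbreeding."""

    sample_ids: np.ndarray
    matrix: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.matrix) - 1.0


def compute_grm(gt: GenotypeTable, maf_min: float = 0.10) -> RelatednessMatrix:
    """Genomic relationship matrix from SNPs with MAF > ``maf_min``.

    Off-diagonal G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i));
    the diagonal uses the inbreeding-form estimator
    1 + (1/m) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).
    Allele frequencies p_i are taken from the non-missing genotypes of the
    input; missing genotypes are skipped per SNP, with m renormalized per
    sample pair.
    """
    if gt.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = gt.alt_frequency()
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(np.nan_to_num(maf) > maf_min)
    if keep.size == 0:
        raise ValueError("no SNP passes the MAF filter (monomorphic-only input?)")

    x = gt.genotypes[:, keep].astype(float)
    obs = x != MISSING
    x[~obs] = 0.0
    p = p[keep]
    denom = 2.0 * p * (1.0 - p)

    # off-diagonals: centered, scaled cross-products over pairwise-observed SNPs
    z = np.where(obs, (x - 2.0 * p) / np.sqrt(denom), 0.0)
    num = z @ z.T
    m_pair = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        G = num / m_pair
    # diagonal: inbreeding-form estimator over each sample's observed SNPs
    diag_terms = np.where(obs, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    m_self = obs.sum(axis=1)
    np.fill_diagonal(G, 1.0 + diag_terms.sum(axis=1) / m_self)
    return RelatednessMatrix(sample_ids=gt.samples["sample_id"].to_numpy(), matrix=G)


def filter_inbred_related(
    grm: RelatednessMatrix, inb_max: float = 0.07, rel_max: float = 0.1
) -> list[str]:
    """Return sample ids retained after inbreeding and relatedness filtering.

    First drops samples with inbreeding (diagonal - 1) above ``inb_max``;
    then, scanning remaining pairs in order of descending relatedness (ties
    broken by sample id), drops the more inbred member of each pair with
    off-diagonal above ``rel_max``.
    """
    ids = list(grm.sample_ids)
    G = grm.matrix
    alive = {i for i in range(len(ids)) if G[i, i] - 1.0 <= inb_max}

    pairs = [
        (G[i, j], i, j)
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if i in alive and j in alive and G[i, j] > rel_max
    ]
    pairs.sort(key=lambda t: (-t[0], ids[t[1]], ids[t[2]]))
    for _, i, j in pairs:
        if i in alive and j in alive:
            if G[i, i] > G[j, j]:
                drop = i
            elif G[j, j] > G[i, i]:
                drop = j
            else:
                drop = max(i, j, key=lambda k: ids[k])
            alive.discard(drop)
    return [ids[i] for i in sorted(alive)]


def relatedness_filter_dataset(
    gt: GenotypeTable,
    metadata: pd.DataFrame,
    plan: GenerationPlan,
    inb_max: float = 0.07,
    rel_max: float = 0.1,
    grm_maf_min: float = 0.10,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply per-generation GRM filtering to a dated dataset.

    Returns the filtered table and metadata with a ``generation`` column.
    Generations with fewer than two samples skip relatedness filtering.
    """
    md = metadata.copy()
    md["generation"] = assign_generations(md["birth_year"].to_numpy(), plan)
    order = {sid: i for i, sid in enumerate(gt.samples["sample_id"])}
    retained: list[str] = []
    for gen, sub in md.groupby("generation"):
        rows = np.asarray([order[s] for s in sub["sample_id"]], dtype=int)
        if len(rows) < 2:
            retained.extend(sub["sample_id"])
            continue
        sub_gt = GenotypeTable(
            variants=gt.variants,
            samples=gt.samples.iloc[rows],
            genotypes=gt.genotypes[rows],
            gq=None if gt.gq is None else gt.gq[rows],
        )
        try:
            grm = compute_grm(sub_gt, maf_min=grm_maf_min)
        except ValueError:
            retained.extend(sub["sample_id"])
            continue
        kept = filter_inbred_related(grm, inb_max=inb_max, rel_max=rel_max)
        logger.info("generation %s: %d/%d samples retained", gen, len(kept), len(rows))
        retained.extend(kept)
    keep_mask = gt.samples["sample_id"].isin(retained).to_numpy()
    out = GenotypeTable(
        variants=gt.variants,
        samples=gt.samples[keep_mask],
        genotypes=gt.genotypes[keep_mask],
        gq=None if gt.gq is None else gt.gq[keep_mask],
    )
    return out, md[md["sample_id"].isin(retained)].reset_index(drop=True)


def build_temporal_counts(
    gt: GenotypeTable, labels: np.ndarray | pd.Series
) -> TemporalCounts:
    """Assemble per-SNP (alt count, total copies) per generation.

    ``labels`` gives each sample's generation (aligned with ``gt.samples``).
    Generations with zero samples overall are dropped; a generation can still
    contribute (0, 0) at individual SNPs where all its genotypes are missing.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != gt.n_samples:
        raise ValueError("labels must align with gt.samples")
    gens = np.unique(labels)
    counts = np.empty((gt.n_snps, gens.size), dtype=int)
    totals = np.empty_like(counts)
    for j, g in enumerate(gens):
        rows = labels == g
        sub = gt.genotypes[rows]
        obs = sub != MISSING
        counts[:, j] = np.where(obs, sub, 0).sum(axis=0)
        totals[:, j] = 2 * obs.sum(axis=0)
    snp_ids = gt.variants["id"].fillna("").to_numpy()
    if (snp_ids == "").any():
        snp_ids = np.asarray(
            [
                sid if sid else f"{c}:{p}"
                for sid, c, p in zip(snp_ids, gt.variants["chrom"], gt.variants["pos"])
            ]
        )
    return TemporalCounts(
        snp_ids=snp_ids,
        generations=gens,
        counts=counts,
        totals=totals,
        variants=gt.variants.copy(),
    )


def maf_filter_temporal(tc: TemporalCounts, maf_min: float = 0.05) -> TemporalCounts:
    """Keep SNPs whose MAF pooled over all sampling times is >= ``maf_min``.

    SNPs with MAF strictly below the threshold are removed ("below 5%"
    removed, boundary kept).
    """
    f = tc.pooled_frequency()
    maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= maf_min)
    logger.info("maf_filter_temporal: %d/%d SNPs kept (MAF >= %g)", keep.size, tc.n_snps, maf_min)
    return tc.take(keep)
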