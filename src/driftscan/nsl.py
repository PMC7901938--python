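"""The nSL haplotype statistic: computation, standardization, outlier calling.

nSL ("number of segregating sites by length") contrasts, at each focal SNP,
the mean pairwise haplotype identity length — measured in SNP counts, which
makes the statistic robust to local recombination-rate variation — between
carriers of the two alleles.  Long shared haplotypes around a high-frequency
allele are the footprint of a recent sweep.  Raw scores are ln(SL_ref /
SL_alt), oriented so every score is positive (redefining the "alternative"
allele where needed), standardized within 20 allele-frequency bins, and
screened with an outlier approach: candidate SNPs exceed a z-score threshold
and are grouped into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class HaplotypeTable:
    """Phased binary haplotypes (rows) x SNPs (columns); positions 1-based bp."""

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.positions.size != self.haplotypes.shape[1]:
            raise ValueError("positions must align with SNP columns")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def alt_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def pair_identity_length(haps: np.ndarray, i: int, j: int, s: int) -> int:
    """SNP-count length of the maximal identical interval of haplotypes i, j around s.

    The interval is contiguous, contains SNP ``s``, and is truncated at the
    chromosome ends; the length is 0 when the pair differs at ``s`` itself.
    """
    if i == j:
        raise ValueError("need two distinct haplotypes")
    row_i, row_j = haps[i], haps[j]
    if row_i[s] != row_j[s]:
        return 0
    mism = np.flatnonzero(row_i != row_j)
    left = mism[mism < s]
    right = mism[mism > s]
    lo = left[-1] + 1 if left.size else 0
    hi = right[0] - 1 if right.size else haps.shape[1] - 1
    return hi - lo + 1


@dataclass(frozen=True)
class NslRecord:
    """nSL at one SNP (raw, oriented and, after binning, standardized)."""

    snp_index: int
    sl_alt: float
    sl_ref: float
    raw_nsl: float
    oriented_score: float
    oriented_freq: float
    defined: bool
    bin_index: int = -1
    std_score: float = float("nan")


def _pair_lengths_all_snps(haps: np.ndarray, max_extension: int | None = None) -> tuple:
    """Identity lengths for every haplotype pair at every SNP.

    Returns (pair index arrays i, j, matrix of shape (n_pairs, n_snps)).
    For each pair the chromosome splits at mismatch positions into maximal
    identical blocks; every SNP inside a block shares the block's length,
    optionally capped at ``max_extension`` SNPs.
    """
    n, m = haps.shape
    ii, jj = np.triu_indices(n, k=1)
    lens = np.zeros((ii.size, m), dtype=float)
    for p, (i, j) in enumerate(zip(ii, jj)):
        diff = haps[i] != haps[j]
        mism = np.flatnonzero(diff)
        bounds = np.concatenate([[-1], mism, [m]])
        for b in range(bounds.size - 1):
            lo, hi = bounds[b] + 1, bounds[b + 1] - 1
            if hi >= lo:
                block_len = hi - lo + 1
                if max_extension is not None:
                    block_len = min(block_len, max_extension)
                lens[p, lo : hi + 1] = block_len
    return ii, jj, lens


def compute_nsl(
    table: HaplotypeTable, max_extension: int | None = None
) -> list[NslRecord]:
    """Raw nSL records for every SNP of a phased haplotype table.

    At SNP s, SL_alt is the mean pairwise identity length over all pairs of
    alt-carrying haplotypes (SL_ref likewise over ref carriers) and raw nSL
    is ln(SL_ref / SL_alt).  The score is undefined when either allele class
    has fewer than two haplotypes.  ``max_extension`` optionally caps the
    identity-interval length (off by default).
    """
    haps = table.haplotypes
    n, m = haps.shape
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    ii, jj, lens = _pair_lengths_all_snps(haps, max_extension=max_extension)

    alt_i = haps[ii].astype(bool)
    alt_j = haps[jj].astype(bool)
    both_alt = alt_i & alt_j
    both_ref = ~alt_i & ~alt_j

    n_alt_pairs = both_alt.sum(axis=0)
    n_ref_pairs = both_ref.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sl_alt = np.where(both_alt, lens, 0.0).sum(axis=0) / n_alt_pairs
        sl_ref = np.where(both_ref, lens, 0.0).sum(axis=0) / n_ref_pairs

    freqs = table.alt_frequency()
    records: list[NslRecord] = []
    for s in range(m):
        defined = n_alt_pairs[s] >= 1 and n_ref_pairs[s] >= 1
        # class sizes: need >= 2 carriers of each allele
        n_alt = int(round(freqs[s] * n))
        defined = defined and n_alt >= 2 and (n - n_alt) >= 2
        if not defined or sl_alt[s] == 0.0 or sl_ref[s] == 0.0:
            records.append(
                NslRecord(s, float("nan"), float("nan"), float("nan"), float("nan"),
                          float(freqs[s]), defined=False)
            )
            continue
        raw = float(np.log(sl_ref[s] / sl_alt[s]))
        records.append(
            NslRecord(
                snp_index=s,
                sl_alt=float(sl_alt[s]),
                sl_ref=float(sl_ref[s]),
                raw_nsl=raw,
                oriented_score=raw,
                oriented_freq=float(freqs[s]),
                defined=True,
            )
        )
    return records


def orient_positive(record: NslRecord) -> NslRecord:
    """Orient a record so its score is non-negative.

    If raw nSL is negative the allele roles are swapped: the score becomes
    -raw and the oriented allele frequency 1 - alt frequency.  Candidates are
    then read from the upper tail only.  Applying twice equals applying once.
    """
    if not record.defined:
        return record
    if record.raw_nsl < 0.0 and record.oriented_score == record.raw_nsl:
        return replace(
            record,
            oriented_score=-record.raw_nsl,
            oriented_freq=1.0 - record.oriented_freq,
        )
    return record


def standardize_bins(
    records: list[NslRecord], n_bins: int = 20, use_oriented_freq: bool = True
) -> list[NslRecord]:
    """Standardize oriented scores within equal-width allele-frequency bins.

    Bins partition (0, 1) into ``n_bins`` equal widths on the oriented
    frequency (or the raw alt frequency with ``use_oriented_freq=False``).
    Bins with fewer than two defined records are merged with their nearest
    non-empty neighbour; a zero-variance bin leaves its scores at 0 with a
    warning.  Undefined records pass through untouched.
    """
    import warnings

    defined = [r for r in records if r.defined]
    if not defined:
        return list(records)
    freqs = np.array(
        [r.oriented_freq if use_oriented_freq else _raw_alt_freq(r) for r in defined]
    )
    scores = np.array([r.oriented_score for r in defined])
    bins = np.clip((freqs * n_bins).astype(int), 0, n_bins - 1)

    # merge under-filled bins into their nearest occupied neighbour
    counts = np.bincount(bins, minlength=n_bins)
    occupied = [b for b in range(n_bins) if counts[b] >= 2]
    if not occupied:
        occupied = [int(np.argmax(counts))]
    remap = {}
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        if b in occupied:
            remap[b] = b
        else:
            remap[b] = min(occupied, key=lambda o: (abs(o - b), o))
    bins = np.array([remap[b] for b in bins])

    std = np.empty_like(scores)
    bin_of = np.empty(len(defined), dtype=int)
    for b in np.unique(bins):
        mask = bins == b
        mu = scores[mask].mean()
        sd = scores[mask].std(ddof=0)
        if sd == 0.0:
            warnings.warn(f"degenerate nSL bin {b}: zero variance, scores set to 0")
            std[mask] = 0.0
        else:
            std[mask] = (scores[mask] - mu) / sd
        bin_of[mask] = b

    out: list[NslRecord] = []
    it = iter(zip(std, bin_of))
    for r in records:
        if r.defined:
            z, b = next(it)
            out.append(replace(r, std_score=float(z), bin_index=int(b)))
        else:
            out.append(r)
    return out


def _raw_alt_freq(r: NslRecord) -> float:
    """Pre-orientation alt frequency of a record."""
    if r.raw_nsl < 0.0 and r.oriented_score == -r.raw_nsl:
        return 1.0 - r.oriented_freq
    return r.oriented_freq


@dataclass(frozen=True)
class CandidateRegion:
    """A run of outlier SNPs grouped by proximity."""

    chrom: str
    start: int
    end: int
    n_candidate_snps: int
    n_strong_snps: int
    max_std_score: float
    tier: str


def call_candidates(
    records: list[NslRecord],
    positions: np.ndarray,
    chrom: str = "1",
    snp_threshold: float = 5.0,
    gap_bp: int = 1_000_000,
    region_min_snps: int = 1,
    strong_threshold: float = 6.0,
    strong_min_snps: int = 10,
) -> list[CandidateRegion]:
    """Group outlier SNPs (std score > ``snp_threshold``) into candidate regions.

    Consecutive candidates at most ``gap_bp`` apart join one region.  A region
    is tier "candidate" when it holds more than ``region_min_snps`` candidate
    SNPs (the dense-data convention is >10; 1 suits sparse panels) and tier
    "strong" when more than ``strong_min_snps`` of its SNPs exceed
    ``strong_threshold``.  Regions below the candidate size are dropped.
    """
    positions = np.asarray(positions, dtype=int)
    cand = [
        (positions[r.snp_index], r.std_score)
        for r in records
        if r.defined and not np.isnan(r.std_score) and r.std_score > snp_threshold
    ]
    if not cand:
        return []
    cand.sort()
    groups: list[list[tuple[int, float]]] = [[cand[0]]]
    for pos, z in cand[1:]:
        if pos - groups[-1][-1][0] <= gap_bp:
            groups[-1].append((pos, z))
        else:
            groups.append([(pos, z)])
    regions = []
    for grp in groups:
        n_cand = len(grp)
        if n_cand < region_min_snps:
            continue
        n_strong = sum(1 for _, z in grp if z > strong_threshold)
        tier = "strong" if n_strong > strong_min_snps else "candidate"
        regions.append(
            CandidateRegion(
                chrom=chrom,
                start=grp[0][0],
                end=grp[-1][0],
                n_candidate_snps=n_cand,
                n_strong_snps=n_strong,
                max_std_score=max(z for _, z in grp),
                tier=tier,
            )
        )
    return regions


def imputation_bias_check(
    regions: list[CandidateRegion],
    positions: np.ndarray,
    imputed_counts: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Check whether candidate regions are enriched in imputed genotypes.

    For each region, compares the mean per-SNP imputed-genotype count of its
    SNPs with the genome-wide distribution via a two-sided permutation test
    (random SNP sets of the same size).  A small p-value flags a region whose
    signal could be an imputation artifact.
    """
    positions = np.asarray(positions, dtype=int)
    imputed_counts = np.asarray(imputed_counts, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome_mean = imputed_counts.mean()
    rows = []
    for r in regions:
        in_region = (positions >= r.start) & (positions <= r.end)
        k = int(in_region.sum())
        obs = imputed_counts[in_region].mean() if k else np.nan
        if k == 0:
            rows.append((r.chrom, r.start, r.end, 0, np.nan, genome_mean, np.nan))
            continue
        perm_means = np.empty(n_permutations)
        for b in range(n_permutations):
            perm_means[b] = imputed_counts[rng.choice(imputed_counts.size, k, replace=False)].mean()
        dev = abs(obs - genome_mean)
        pval = (1 + np.sum(np.abs(perm_means - genome_mean) >= dev - 1e-12)) / (n_permutations + 1)
        rows.append((r.chrom, r.start, r.end, k, obs, genome_mean, float(pval)))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "mean_imputed", "genome_mean", "pvalue"],
    )


def records_to_frame(records: list[NslRecord], positions: np.ndarray, chrom: str = "1") -> pd.DataFrame:
    positions = np.asarray(positions, dtype=int)
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": int(positions[r.snp_index]),
                "snp_index": r.snp_index,
                "sl_alt": r.sl_alt,
                "sl_ref": r.sl_ref,
                "raw_nsl": r.raw_nsl,
                "oriented_score": r.oriented_score,
                "oriented_freq": r.oriented_freq,
                "bin": r.bin_index,
                "std_nsl": r.std_score,
                "defined": r.defined,
            }
            for r in records
        ]
    )
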