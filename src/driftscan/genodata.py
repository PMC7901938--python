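"""Reading, cleaning and merging multi-source SNP genotype data.

Genotypes from several genotyping technologies (dense/sparse SNP chips,
whole-genome sequencing) are held in a single container, cleaned by genotype
quality and per-variant missingness, and merged on position with ref/alt
reconciliation.  Strand-ambiguous (A/T, G/C) allele swaps cannot be told apart
from genuine inversions, so they are never auto-reconciled; a dedicated
discordance flag catches them downstream.

Genotype codes are alt-allele dosages {0, 1, 2}; missing is ``MISSING`` (-1).
Coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: complement lookup for strand-ambiguity checks
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP site. ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def strand_ambiguous(self) -> bool:
        """True for A/T and G/C SNPs, whose strand flips are undetectable."""
        return _COMPLEMENT.get(self.ref) == self.alt


@dataclass
class GenotypeTable:
    """Samples x biallelic SNPs with alt-allele dosage codes.

    Attributes
    ----------
    variants
        DataFrame with columns chrom, pos, ref, alt, id (one row per SNP).
    samples
        DataFrame with columns sample_id, source.
    genotypes
        int8 array of shape (n_samples, n_snps); values in {0, 1, 2, MISSING}.
    gq
        Optional float array of the same shape with phred-scaled genotype
        qualities (NaN where no GQ was recorded).
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    swap_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")
        if self.gq is not None:
            self.gq = np.asarray(self.gq, dtype=float)
            if self.gq.shape != self.genotypes.shape:
                raise ValueError("gq shape differs from genotype shape")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def variant_objs(self) -> list[Variant]:
        return [
            Variant(r.chrom, int(r.pos), r.ref, r.alt, r.id)
            for r in self.variants.itertuples(index=False)
        ]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return (self.genotypes == MISSING).mean(axis=0)

    def alt_frequency(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing genotypes (NaN if none)."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        obs = g != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs, g, 0).sum(axis=0) / (2.0 * n)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            variants=self.variants.copy(),
            samples=self.samples.copy(),
            genotypes=self.genotypes.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            swap_log=list(self.swap_log),
        )

    def take_variants(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            variants=self.variants.iloc[idx],
            samples=self.samples,
            genotypes=self.genotypes[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            swap_log=list(self.swap_log),
        )


def gq_to_error_prob(gq: float | np.ndarray) -> float | np.ndarray:
    """Convert phred-scaled genotype quality to error probability 10^(-GQ/10).

    GQ = 10 corresponds to a 0.1 probability that the call is wrong.
    """
    gq_arr = np.asarray(gq, dtype=float)
    if np.any(gq_arr < 0):
        raise ValueError("GQ must be non-negative")
    out = 10.0 ** (-gq_arr / 10.0)
    return float(out) if np.isscalar(gq) or out.ndim == 0 else out


def mask_low_gq(gt: GenotypeTable, threshold: float = 10.0) -> GenotypeTable:
    """Set genotypes with GQ strictly below ``threshold`` to missing.

    Genotypes without a recorded GQ (NaN) are left untouched.
    """
    if gt.gq is None:
        return gt.copy()
    out = gt.copy()
    low = np.nan_to_num(out.gq, nan=np.inf) < threshold
    out.genotypes[low] = MISSING
    logger.info("mask_low_gq: %d genotypes set missing (GQ < %g)", int(low.sum()), threshold)
    return out


def filter_missingness(gt: GenotypeTable, max_missing_frac: float) -> GenotypeTable:
    """Drop variants whose missing fraction strictly exceeds ``max_missing_frac``.

    The boundary is kept: a SNP with exactly the threshold fraction missing
    survives ("more than X%" removed).
    """
    frac = gt.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing_frac)
    logger.info(
        "filter_missingness: %d/%d variants kept at threshold %g",
        len(keep), gt.n_snps, max_missing_frac,
    )
    return gt.take_variants(keep)


def merge_sources(tables: list[GenotypeTable]) -> GenotypeTable:
    """Merge genotype tables from different sources on (chrom, pos).

    A variant is retained only if present in every table with identical
    ref/alt, or identical after a ref/alt swap — in which case the swapped
    table's genotypes are recoded g -> 2-g and the swap is logged.
    Strand-ambiguous SNPs (A/T, G/C) are never swap-reconciled: a swapped
    ambiguous pair looks identical on the other strand, so such variants pass
    through unchanged and are left to ``flag_discordant_snps``.  Irreconcilable
    allele pairs exclude the variant (logged, not fatal).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to merge")
    all_ids = pd.concat([t.samples["sample_id"] for t in tables])
    if all_ids.duplicated().any():
        raise ValueError("sample ids must be disjoint across tables")

    keys = [
        {(r.chrom, r.pos): i for i, r in enumerate(t.variants.itertuples(index=False))}
        for t in tables
    ]
    common = [k for k in keys[0] if all(k in km for km in keys[1:])]
    # deterministic order: first table's variant order
    base = tables[0]

    kept_cols: list[list[int]] = [[] for _ in tables]
    flip_masks: list[list[bool]] = [[] for _ in tables]
    swap_log: list[tuple] = []
    n_irrec = 0
    for key in common:
        i0 = keys[0][key]
        v0 = base.variants.iloc[i0]
        ok = True
        flips = [False] * len(tables)
        for t_idx in range(1, len(tables)):
            vi = tables[t_idx].variants.iloc[keys[t_idx][key]]
            if vi.ref == v0.ref and vi.alt == v0.alt:
                continue
            if vi.ref == v0.alt and vi.alt == v0.ref:
                ambiguous = _COMPLEMENT.get(v0.ref) == v0.alt
                if ambiguous:
                    # an apparent swap at an A/T or G/C SNP may equally be a
                    # strand flip; keep genotypes unrecoded and let
                    # flag_discordant_snps catch any resulting inversion
                    swap_log.append((key, "ambiguous-swap-passed-through"))
                else:
                    flips[t_idx] = True
                    swap_log.append((key, f"refalt-swap table {t_idx}"))
            else:
                ok = False
                n_irrec += 1
                swap_log.append((key, "irreconcilable-excluded"))
                break
        if ok:
            for t_idx in range(len(tables)):
                kept_cols[t_idx].append(keys[t_idx][key])
                flip_masks[t_idx].append(flips[t_idx])

    geno_blocks, gq_blocks = [], []
    any_gq = any(t.gq is not None for t in tables)
    for t_idx, t in enumerate(tables):
        cols = np.asarray(kept_cols[t_idx], dtype=int)
        g = t.genotypes[:, cols].copy()
        fl = np.asarray(flip_masks[t_idx], dtype=bool)
        if fl.any():
            sub = g[:, fl]
            obs = sub != MISSING
            sub[obs] = 2 - sub[obs]
            g[:, fl] = sub
        geno_blocks.append(g)
        if any_gq:
            q = t.gq[:, cols] if t.gq is not None else np.full(g.shape, np.nan)
            gq_blocks.append(q)

    variants = base.variants.iloc[np.asarray(kept_cols[0], dtype=int)]
    samples = pd.concat([t.samples for t in tables], ignore_index=True)
    logger.info(
        "merge_sources: %d common variants, %d kept, %d excluded, %d swaps recoded",
        len(common), len(variants), n_irrec,
        sum(1 for _, what in swap_log if what.startswith("refalt-swap")),
    )
    return GenotypeTable(
        variants=variants,
        samples=samples,
        genotypes=np.vstack(geno_blocks),
        gq=np.vstack(gq_blocks) if any_gq else None,
        swap_log=swap_log,
    )


@dataclass(frozen=True)
class DiscordantFlag:
    variant: Variant
    snp_index: int
    source_high: str
    source_low: str
    freq_high: float
    freq_low: float
    strand_ambiguous: bool


def flag_discordant_snps(gt: GenotypeTable, eps: float = 0.05) -> list[DiscordantFlag]:
    """Flag SNPs nearly fixed for opposite alleles in different source groups.

    A SNP is flagged when some source shows alt frequency >= 1-eps while
    another shows alt frequency <= eps — the signature of a ref/alt inversion
    introduced when merging datasets.  The flag records whether the SNP is
    strand-ambiguous (A/T or G/C), the typical culprit.  Flagged SNPs should be
    excluded from downstream time-series testing.
    """
    sources = gt.samples["source"].unique()
    freqs = {}
    for src in sources:
        mask = (gt.samples["source"] == src).to_numpy()
        freqs[src] = gt.alt_frequency(sample_mask=mask)
    flags: list[DiscordantFlag] = []
    var_objs = gt.variant_objs()
    for j in range(gt.n_snps):
        hi = [(s, freqs[s][j]) for s in sources if freqs[s][j] >= 1.0 - eps]
        lo = [(s, freqs[s][j]) for s in sources if freqs[s][j] <= eps]
        if hi and lo:
            v = var_objs[j]
            flags.append(
                DiscordantFlag(
                    variant=v,
                    snp_index=j,
                    source_high=hi[0][0],
                    source_low=lo[0][0],
                    freq_high=float(hi[0][1]),
                    freq_low=float(lo[0][1]),
                    strand_ambiguous=v.strand_ambiguous,
                )
            )
    logger.info("flag_discordant_snps: %d variants flagged (eps=%g)", len(flags), eps)
    return flags


# ---------------------------------------------------------------------------
# VCF and metadata I/O


def write_vcf(gt: GenotypeTable, path: str) -> None:
    """Write the table as an uncompressed VCF v4.2 (GT and, if present, GQ)."""
    has_gq = gt.gq is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        for chrom in pd.unique(gt.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(gt.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:GQ" if has_gq else "GT"
        for j, r in enumerate(gt.variants.itertuples(index=False)):
            vid = r.id if r.id else "."
            fields = [str(r.chrom), str(r.pos), str(vid), r.ref, r.alt, ".", ".", ".", fmt]
            for i in range(gt.n_samples):
                cell = gt_strings[int(gt.genotypes[i, j])]
                if has_gq:
                    q = gt.gq[i, j]
                    cell += ":." if np.isnan(q) else f":{int(round(q))}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str, source: str = "unknown") -> GenotypeTable:
    """Read a VCF into a GenotypeTable, labelling all samples with ``source``.

    Only biallelic SNPs are retained; GT is translated to alt dosage and GQ
    (when present in FORMAT) is kept per genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, genos, gqs = [], [], []
    saw_gq = False
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "id": rec.ID,
            }
        )
        types = np.asarray(rec.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = np.select([types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING)
        genos.append(g.astype(np.int8))
        try:
            q = rec.format("GQ")
        except KeyError:
            q = None
        if q is not None:
            q = np.asarray(q, dtype=float).reshape(-1)
            q[q < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
            saw_gq = True
            gqs.append(q)
        else:
            gqs.append(np.full(len(sample_ids), np.nan))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    samples = pd.DataFrame({"sample_id": sample_ids, "source": source})
    genotypes = (
        np.asarray(genos, dtype=np.int8).T
        if genos
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    gq = np.asarray(gqs, dtype=float).T if (gqs and saw_gq) else None
    return GenotypeTable(variants=variants, samples=samples, genotypes=genotypes, gq=gq)


def read_metadata(path: str) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, birth_year, source)."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "source": str})
    required = {"sample_id", "birth_year", "source"}
    if not required.issubset(md.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return md


def write_metadata(md: pd.DataFrame, path: str) -> None:
    md.to_csv(path, sep="\t", index=False)
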