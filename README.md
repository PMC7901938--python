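# driftscan

Selection scans for populations sampled over a few dozen years — the
situation of livestock breeds and gene-bank collections where genotypes
exist for animals born across many generations.  Allele-frequency
trajectories over the last generations carry information about *recent*
selection that present-day data alone cannot provide; haplotype statistics
on present-day data see *older* sweeps.  `driftscan` implements both prongs
and a forward-in-time Wright–Fisher simulator to validate them end to end:

* **Temporal scan** — generation-binned allele counts are modelled with a
  Wright–Fisher hidden Markov model: the hidden population frequency
  evolves by `k' ~ Binomial(2Ne, p')` with genic selection
  `p' = p(1+s)/(1+ps)`, and observed counts are binomial samples from it.
  Per SNP, a likelihood-ratio test of `s ≠ 0` vs `s = 0` gives a χ²(1)
  p-value; effective population size Ne is estimated first by multi-locus
  maximum likelihood with a profile-likelihood CI.  P-values are aggregated
  along chromosomes by the **local score**: scores `X = −log10(p) − 1` feed
  the Lindley process `H_i = max(0, H_{i−1} + X_i)`, and excursions above a
  chromosome-wide threshold (Monte-Carlo calibrated, with a Cramér-type
  closed form as cross-check) become candidate regions.
* **nSL scan** — on phased haplotypes, `nSL = ln(SL_ref/SL_alt)` contrasts
  mean pairwise haplotype-identity lengths (in SNP counts) between carriers
  of the two alleles at each SNP; scores are oriented positive, standardized
  within 20 allele-frequency bins, and outliers (z > 5, strong tier z > 6)
  are grouped into regions.
* **Data handling** — multi-source VCFs (chip-like and sequencing-like) are
  cleaned by genotype quality (GQ < 10 masked, `GQ = −10·log10(P_wrong)`),
  filtered by per-variant missingness (>40% for sequencing-like, >5% for
  chip-like sources), merged on position with ref/alt-swap reconciliation
  (never at strand-ambiguous A/T–G/C SNPs), and audited for discordant
  near-fixed frequencies between sources.  Samples are binned into 4-year
  generations by birth year and pruned of inbred (F > 0.07) and related
  (r > 0.1) animals via a genomic relationship matrix per generation.

See `docs/methods.md` for model details, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth:

```sh
python analysis/01_simulate.py          # three sources, 8 generations, 1 sweep
python analysis/02_preprocess.py       # clean, merge, relatedness filter, counts
python analysis/03_scan_temporal.py    # Ne estimate, LRT scan, regions
python analysis/04_scan_nsl.py         # nSL scan on the phased panel
python analysis/05_report.py           # top-SNP trajectories, joint summary
```

A run with the default seed (42) prints, in `03_scan_temporal.py`:

```
Ne estimate (all SNPs): 169.3 (95% CI 124-243)
Ne estimate (excluding 6 SNPs in called regions): 703.5 (95% CI 299-800)
tested SNPs: 343; smallest p-value 1.45e-08
snp_id    s_hat       lrt       pvalue
  sel4 0.597963 32.115111 1.453027e-08
  sel3 0.507115 24.303019 8.230994e-07
  sel0 0.447693 20.757105 5.213779e-06
  sel2 0.468270 19.410809 1.054088e-05
  sel5 0.403629 17.781101 2.478328e-05
regions at alpha=0.10: 1
chrom  start_bp   end_bp  length_kbp  n_snps      peak  threshold  alpha
    1  10001000 10006000         5.0       6 25.707003   2.782081    0.1
```

The simulation placed six SNPs under selection at `s = 0.5` (ids `sel*`)
among 450 neutral ones at true Ne = 400.  The scan ranks exactly those SNPs
on top with ŝ near 0.5 each, and the local score calls the one region
holding them.  The two Ne estimates bracket the truth and illustrate a real
effect: selected loci inflate apparent drift, biasing Ne downward, so the
script re-estimates after excluding called regions (the profile is flat at
these sample sizes — 8 generations of ~13 diploids carry limited drift
information — hence the wide intervals).  `04_scan_nsl.py` recovers the
injected sweep: the focal SNP (position 1001000) is the top standardized
score (z = 4.67) and an 8-SNP candidate region spans 982–1036 kb around it.
`05_report.py` exports the observed frequency trajectories of each test's
top-5 SNPs, e.g. `sel4: 0.17 → 0.17 → 0.27 → 0.32 → 0.36 → 0.69 → 0.82 →
0.73` (`results/top_snp_trajectories.tsv`).

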