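# Methods

`mosaic11p` quantifies somatic mosaicism of the imprinted 11p15.5 locus
(IGF2/H19 under IC1; KCNQ1OT1/CDKN1C under IC2) in non-tumor liver tissue
from four independent measurement modalities, and ships a synthetic-data
generator whose mixture models are the generative counterparts of the
estimators, so every stage is testable without sequencing data.

## Bulk allele-dosage model

At a germline heterozygous SNP inside an altered interval, a fraction
`rho` of altered cells shifts the expected frequency of the gained allele
to

- cn-LOH (paternal uniparental disomy, `N_maj=2, N_min=0`):
  `d = (1 + rho) / 2`
- paternal duplication (`N_maj=2, N_min=1`): `d = (1 + rho) / (2 + rho)`

Both are special cases of the general dosage relation, which inverts to

```
% cells altered = 100 * (2*GAF - 1) / (GAF*(2 - N_maj - N_min) + N_maj - 1)
```

where `GAF` is the **median** non-tumor B-allele frequency of the gained
alleles (the median, not the mean, is used deliberately: it is robust to
outlier sites and to residual homozygous contamination). Which allele is
"gained" at each SNP is read off the matched tumor, where the alteration is
(near-)clonal: sites with tumor BAF > 0.5 track the alternate allele, < 0.5
the reference allele, and exact ties or undefined tumor BAFs are dropped.

Detection aggregates the gained-allele and total reads over all informative
SNPs and computes a one-sided exact binomial tail `P(X >= k | n, 0.5)`
(`scipy.stats.binomtest`). A single aggregated test is used rather than
combining per-SNP tests: it matches the read-summing logic of the
single-nucleus caller and maximizes power at low `rho`; per-SNP tail
p-values are still emitted for inspection. Estimates that fall outside
[0, 100] (sampling noise near `rho = 0` produces small negatives) are
clamped with a warning, and the raw value is kept on the estimate object.

**Heterozygosity filter.** Germline heterozygosity is decided by requiring
BAF in [0.2, 0.8] at depth >= 8 in a designated reference sample. The
preferred reference is an unaltered germline sample (blood): filtering on
the non-tumor tissue itself truncates the gained-allele BAF distribution
once the mosaic fraction is large (at `rho = 0.58` the gained dosage 0.79
sits next to the 0.8 window edge), biasing the median downward. When only
the non-tumor tissue is available the model still runs, but it warns
whenever the estimated fraction exceeds 40%.

**Area-based fraction.** For annotated stained sections the fraction is
simply `100 * mosaic_area / total_area`.

## Imprinting-center methylation

IC1 is paternally methylated and IC2 maternally methylated, so normal
tissue sits near a common baseline `b` on both (approximately 0.6 in fetal
liver) and the IC1/IC2 ratio is ~1. Paternal UPD moves the two centers
symmetrically (`IC1 = b(1-rho) + rho`, `IC2 = b(1-rho)`), giving the
methylation-based estimator

```
% cells altered = 100 * (IC1 - IC2) / (IC1 + IC2)
```

This recovers `rho` exactly when `b = 0.5`. With the empirically observed
`b ≈ 0.6` baseline the estimator is biased (it returns
`rho / (1.2 - 0.2*rho)` under cn-LOH); the generator can produce either
baseline so the bias is measurable. IC means are arithmetic means of the
non-excluded MS-MLPA probes per center; probe `H19.11.001.976583` is
excluded by default because its distribution does not separate samples with
and without IC1 gain of methylation. RRBS region methylation is the
pooled-count ratio `sum(meth) / sum(meth + unmeth)` over in-region CpGs —
not the mean of per-CpG ratios — which weighs deep CpGs more and is
invariant to splitting a CpG's counts across records. Known biased CpG
sites can be supplied as an exclusion list; default IC1/IC2 intervals are
chr11:1,998,745–2,003,509 and chr11:2,697,587–2,700,983 (hg38), editable
via BED input.

**Epimutation calls.** Per probe, a two-cluster 1-D k-means across the
cohort defines a threshold at the midpoint of the two cluster means. A
sample is called GOM-IC1 when at least 2 of its 3 usable IC1 probes lie
above their thresholds, and LOM-IC2 when at least 2 of 4 IC2 probes lie
below theirs (the loss direction). The k-means is computed exactly: in one
dimension the optimal 2-means partition is always a contiguous split of the
sorted values, so the implementation scans all n−1 splits for the minimal
within-cluster sum of squares. This is deterministic and globally optimal,
unlike percentile-initialised Lloyd iteration, which we found converges to
local optima on small overlapping cohorts. Probes with degenerate
(single-valued) distributions define no threshold and never count as hits.
Note the thresholds are cohort-relative: a meaningful call requires the
cohort to contain both affected and unaffected samples for the center in
question.

**Ratio outlier flag.** With a cohort of presumed-normal ratios, a sample
is flagged mosaic when its IC1/IC2 ratio lies strictly beyond
mean ± 3 SD (both directions, capturing IC1-gain-driven elevation and
maternal-side anomalies); the multiplier `k_sd` is exposed.

## Single-nucleus cn-LOH genotyping

Heterozygous SNPs (same filter as the bulk model) with tumor allelic
disequilibrium are phased: the majority tumor allele is the duplicated
paternal (PAT) haplotype, the minority allele the lost maternal (MAT)
haplotype. Reads per nucleus are summed over phased SNPs per haplotype;
counts are treated as deduplicated units (no internal UMI collapsing). The
per-cell BAF is `PAT / (PAT + MAT)`, and cells with at least 8 informative
reads are called `cn_LOH` when BAF >= 0.85 (inclusive), `no_cnLOH` when
BAF <= 0.60 (inclusive), and `unknown` otherwise; cells under 8 reads are
`unknown`. Cells from a patient whose tumor carries no cn-LOH are reference
negatives regardless of counts. Per-cell-type summaries report the mean
BAF and the cn-LOH fraction over determinate calls only (0 when every call
is unknown), with unknown counts always shown. Cell-type labels are
user-supplied free text; upstream clustering is out of scope.

## IGF2 promoter usage

Each promoter category (adult P0-P1; fetal P2, P3, P4) is summarized by the
maximum splice-junction depth over its category-specific junctions; the
universal depth is the maximum over junctions shared by all transcripts.
Category depths are divided by the universal depth — within one sample this
normalization cancels in the proportions, but the normalized values are
emitted for cross-sample comparison of absolute promoter activity — and
proportions are the normalized values divided by their sum. The fetal
fraction is the P2+P3+P4 proportion. All-zero categories yield an absent
usage rather than a 0/0. The junction-to-category map is a configuration
table, since categories are defined by transcript structure rather than by
fixed coordinates.

## Synthetic-data generator

`ScenarioConfig` requires an explicit seed; fixed seeds give byte-identical
outputs. Defaults encode the targeted sequencing design:

| parameter | default | meaning |
|---|---|---|
| `n_snps` | 5,000 | heterozygous SNPs in the locus |
| `depth_nt` / `depth_t` | 30 / 90 | mean non-tumor / tumor coverage |
| `tumor_purity` | 1.0 | altered fraction in the tumor sample |
| `with_germline` | True | emit a balanced blood-like reference |
| `overdispersion` | 0.0 | beta-binomial over-dispersion (capture data are overdispersed; off by default) |
| `ic_baseline` / `probe_noise_sd` | 0.5 / 0.05 | imprinting baseline, probe noise |
| `n_samples` / `n_altered` | 30 / 5 | MS-MLPA cohort composition |
| `n_cells` / `reads_per_cell_mean` | 1,000 / 20 | nuclei and informative reads |
| `error_rate` | 0.02 | haplotype-assignment error per read |
| `usage_vector` / `junction_depth` | (0.1,0.3,0.4,0.2) / 10,000 | promoter usage, junction sampling depth |

Read depths are Poisson-distributed around the configured mean. This
matters: at a constant depth of 30 the BAF support is the lattice k/30 and
the median-based GAF cannot resolve a 3% mosaic fraction; heterogeneous
depths, as in real sequencing, restore consistency. Methylation mixtures
are defined for cn-LOH (altered cells IC1=1, IC2=0) and the two
epimutations (one center moved only); no methylation mixture is defined for
a paternal duplication, which the generator rejects. Probe noise is
truncated Gaussian — simple, bounded, and sufficient for threshold testing.

What the generator does **not** emulate: linkage between neighboring SNPs,
mapping and genotyping artifacts, GC/capture bias beyond the optional
beta-binomial, ambient RNA and doublets in nuclei, batch effects between
methylation runs. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed sampling models, not
robustness to every artifact of real data.

## Numerical choices and conventions

- Coordinates are 1-based inclusive everywhere internally; BED input is
  converted on read. Genome build is free-text metadata, never interpreted.
- Even-count medians are the midpoint of the middle pair.
- Threshold boundaries: the heterozygosity window and the per-cell BAF
  thresholds are inclusive; tumor orientation and the ratio outlier rule
  are strict inequalities.
- Degenerate inputs (zero depth, empty site lists, all-zero junction
  categories, single-valued probe distributions) are flagged or raised,
  never silently imputed.
- Estimated fractions are clamped to [0, 100] with the raw value retained.

## Problem sizes

The default test and verification runs use 5,000 SNPs per cohort (20 seeds
per mosaic fraction; 1,000 cohorts for the null calibration), 3,000 nuclei
per single-cell scenario, 30-sample methylation cohorts over 20 seeds, and
10,000-read junction sampling. These sizes put Monte-Carlo error well
inside the stated tolerance bands (e.g. the GAF median SE is ~0.2
percentage points of mosaic fraction at 5,000 × 30×).

## Known limitations

- The methylation fraction estimator assumes a symmetric 0.5 baseline;
  report the bias above when interpreting tissues with shifted baselines.
- Epimutation thresholds are cohort-relative; singleton cohorts get no
  epimutation calls.
- The bulk model estimates a single locus per run; genome-wide scanning,
  copy-number segmentation and purity estimation are out of scope.
- The NT-self heterozygosity filter is biased at high mosaicism (warned at
  >40%); provide a germline reference where possible.
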