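# mosaic11p

Detection and quantification of **mosaic 11p15.5 alterations** in non-tumor
liver tissue. The imprinted 11p15.5 locus (IGF2/H19 controlled by imprinting
center IC1, KCNQ1OT1/CDKN1C by IC2) can be altered in a fraction of cells by
early post-zygotic events — copy-neutral LOH (paternal uniparental disomy),
paternal duplication, or IC1/IC2 epimutations. Such pre-malignant mosaic
expansions matter clinically in young children with hepatoblastoma, where
the fraction of altered cells ranges from a few percent to more than half
the tissue. This package is for computational biologists who need to
detect that mosaicism and estimate its cell fraction from standard
processed data: SNP allele counts, targeted/bisulfite methylation values,
single-nucleus allele counts, splice-junction depths, or annotated section
areas.

## The model

A fraction `ρ` of altered cells shifts the gained-allele frequency at
germline heterozygous SNPs to `(1+ρ)/2` under cn-LOH and `(1+ρ)/(2+ρ)`
under paternal duplication. Inverting the general dosage relation,

```
% cells altered = 100 · (2·GAF − 1) / (GAF·(2 − N_maj − N_min) + N_maj − 1)
```

with `GAF` the median non-tumor B-allele frequency of the alleles gained in
the matched tumor and `(N_maj, N_min)` the allele copy numbers of the
alteration (cn-LOH: `100·(2·GAF − 1)`). Detection is a one-sided exact
binomial test of the aggregated gained reads against p = 0.5. The
methylation counterpart is `100·(IC1 − IC2)/(IC1 + IC2)`; single nuclei are
genotyped from phased paternal/maternal read counts (≥8 reads, BAF ≥ 0.85
→ cn-LOH, ≤ 0.60 → no cn-LOH); IGF2 promoter usage is the proportion of
normalized splice-junction depths over the adult (P0-P1) and fetal
(P2/P3/P4) promoter categories. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Simulate a 30% cn-LOH mosaic liver (5,000 heterozygous SNPs, 30× non-tumor
/ 90× tumor coverage, matched blood reference) and estimate the fraction:

```python
from mosaic11p import BulkMosaicModel, ScenarioConfig, simulate_bulk_snps

sites, truth = simulate_bulk_snps(ScenarioConfig(seed=7, rho=0.30))
res = BulkMosaicModel(sites).fit()
print(res.summary())
```

```
Bulk BAF mosaicism estimate
===========================
locus            chr11:1-2800000 (cn_LOH)
informative SNPs 4993
GAF (non-tumor)  0.6500
fraction altered 30.00 %
binomial p-value 0
detected (a=0.05) True
```

The gained-allele frequency 0.65 is the cn-LOH mixture dosage
`(1+ρ)/2` at `ρ = 0.30`, so the estimator returns 30% of cells altered;
the binomial p-value underflows to 0 at this depth, i.e. detection is
unambiguous. The same Model/Results pattern serves the other modalities
(`MethylationModel`, `SingleCellLohModel`, `PromoterUsageModel`), and a
`mosaic11p` console script exposes `simulate`, `bulk-detect`, `methyl`,
`sc-call`, `promoters` and `report` subcommands; `report` runs configured
stages end to end and writes a cross-modality concordance table with the
per-sample spread of fraction estimates.

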