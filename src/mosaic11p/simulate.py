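"""Synthetic data with the statistical structure the estimators assume.

The mixture models here are the generative counterparts of the analysis
formulas, so they double as oracles for parameter recovery:

* bulk SNPs — germline heterozygous sites whose gained-allele dosage in the
  mixed tissue is (1+rho)/2 under cn-LOH or (1+rho)/(2+rho) under paternal
  duplication; read counts are binomial (optionally beta-binomial) at
  Poisson-distributed depths around the configured mean coverage;
* MS-MLPA probes — IC1/IC2 probe values drawn around the mixture means
  (cn-LOH cells: IC1=1, IC2=0; epi_IC1 cells: IC1=1 only; epi_IC2 cells:
  IC2=0 only) with truncated Gaussian noise;
* single-nucleus allele counts — each cell is LOH with probability rho and
  emits paternal-haplotype reads with probability 1-error_rate (0.5 when
  balanced) at Poisson read depth;
* splice junctions — multinomial category depths under a fixed promoter
  usage vector.

Every generator takes an explicit seed through :class:`ScenarioConfig`
(no silent nondeterminism) and returns a truth record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk import IMPRINTED_11P15, LocusSpec
from .promoters import CATEGORIES, JunctionCounts

__all__ = [
    "ScenarioConfig",
    "gained_dosage",
    "simulate_bulk_snps",
    "simulate_methylation",
    "simulate_cells",
    "simulate_junctions",
]

METHYLATION_ALTERATIONS = ("none", "cn_LOH", "epi_IC1", "epi_IC2")

#: MS-MLPA probe layout of the targeted 11p15.5 methylation kit: 4 IC1
#: probes (one excluded from analysis by default), 4 IC2, 2 IGF2 promoter.
MLPA_PROBES = (
    ("IC1_A", "IC1"),
    ("IC1_B", "IC1"),
    ("IC1_C", "IC1"),
    ("H19.11.001.976583", "IC1"),
    ("IC2_A", "IC2"),
    ("IC2_B", "IC2"),
    ("IC2_C", "IC2"),
    ("IC2_D", "IC2"),
    ("IGF2P_A", "IGF2_promoter"),
    ("IGF2P_B", "IGF2_promoter"),
)


@dataclass
class ScenarioConfig:
    """Study conditions for the synthetic generators.

    ``seed`` is mandatory.  Defaults mirror the sequencing design the
    estimators target: 5,000 heterozygous SNPs at 30x mean non-tumor and
    90x mean tumor coverage, a matched unaltered germline (blood-like)
    sample, probe noise SD 0.05 around a 0.5 imprinting baseline, 1,000
    nuclei at a mean of 20 informative reads with a 2% haplotype error
    rate, and 10,000-read junction sampling.
    """

    seed: int
    rho: float = 0.30
    alteration: str = "cn_LOH"
    n_snps: int = 5000
    depth_nt: float = 30.0
    depth_t: float = 90.0
    tumor_purity: float = 1.0
    with_germline: bool = True
    overdispersion: float = 0.0
    locus: LocusSpec = field(default_factory=lambda: IMPRINTED_11P15)
    # methylation cohort
    ic_baseline: float = 0.5
    probe_noise_sd: float = 0.05
    n_samples: int = 30
    n_altered: int = 5
    # single-nucleus
    n_cells: int = 1000
    n_phased_snps: int = 40
    reads_per_cell_mean: float = 20.0
    error_rate: float = 0.02
    # junctions
    usage_vector: tuple = (0.1, 0.3, 0.4, 0.2)
    junction_depth: int = 10000
    universal_depth: int = 10000

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed is mandatory and must be an integer")
        for name in ("rho", "tumor_purity", "ic_baseline", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.error_rate >= 0.5:
            raise ValueError("error_rate must be < 0.5")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion must lie in [0, 1)")
        if abs(sum(self.usage_vector) - 1.0) > 1e-9 or len(self.usage_vector) != 4:
            raise ValueError("usage_vector must be 4 proportions summing to 1")


def gained_dosage(rho: float, alteration: str) -> float:
    """Expected gained-allele frequency in a tissue with fraction rho altered.

    cn-LOH: (1+rho)/2 (the altered cells carry two gained copies, zero
    lost); paternal duplication: (1+rho)/(2+rho) (three copies, two gained).
    """
    if alteration == "cn_LOH":
        return (1.0 + rho) / 2.0
    if alteration == "paternal_dup":
        return (1.0 + rho) / (2.0 + rho)
    raise ValueError(f"unknown copy-number alteration {alteration!r}")


def _sample_reads(rng, depth_mean: float, p: np.ndarray, overdispersion: float):
    """Alt-read counts at Poisson depths; beta-binomial when overdispersed."""
    n = rng.poisson(depth_mean, size=p.shape)
    if overdispersion > 0:
        conc = (1.0 - overdispersion) / overdispersion
        a = np.clip(p * conc, 1e-9, None)
        b = np.clip((1.0 - p) * conc, 1e-9, None)
        p = rng.beta(a, b)
    alt = rng.binomial(n, p)
    return n - alt, alt


def simulate_bulk_snps(cfg: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Matched non-tumor/tumor (and optional germline) SNP allele counts.

    Each site is germline heterozygous; the gained haplotype carries the ref
    or alt allele with equal probability.  Non-tumor counts follow the
    mosaic dosage at ``rho``; tumor counts follow the fully altered dosage
    at ``tumor_purity``; the germline sample is balanced (dosage 0.5).
    Returns the site table and a truth record with rho and the per-site
    gained-allele orientation.
    """
    if cfg.alteration not in ("cn_LOH", "paternal_dup"):
        raise ValueError("bulk simulation requires a copy-number alteration")
    rng = np.random.default_rng(cfg.seed)
    span = cfg.locus.end - cfg.locus.start + 1
    pos = np.sort(rng.choice(span, size=cfg.n_snps, replace=False)) + cfg.locus.start
    gained_is_alt = rng.random(cfg.n_snps) < 0.5
    d_nt = gained_dosage(cfg.rho, cfg.alteration)
    d_t = gained_dosage(cfg.tumor_purity, cfg.alteration)
    p_alt_nt = np.where(gained_is_alt, d_nt, 1.0 - d_nt)
    p_alt_t = np.where(gained_is_alt, d_t, 1.0 - d_t)
    ref_nt, alt_nt = _sample_reads(rng, cfg.depth_nt, p_alt_nt, cfg.overdispersion)
    ref_t, alt_t = _sample_reads(rng, cfg.depth_t, p_alt_t, cfg.overdispersion)
    sites = pd.DataFrame(
        {
            "chrom": cfg.locus.chrom,
            "pos": pos,
            "ref_nt": ref_nt,
            "alt_nt": alt_nt,
            "ref_t": ref_t,
            "alt_t": alt_t,
        }
    )
    if cfg.with_germline:
        ref_gl, alt_gl = _sample_reads(
            rng, cfg.depth_nt, np.full(cfg.n_snps, 0.5), cfg.overdispersion
        )
        sites["ref_gl"] = ref_gl
        sites["alt_gl"] = alt_gl
    truth = {
        "rho": cfg.rho,
        "alteration": cfg.alteration,
        "gained_dosage_nt": d_nt,
        "gained_is_alt": gained_is_alt,
        "locus": cfg.locus,
    }
    return sites, truth


def methylation_mixture_means(alteration: str, rho: float, baseline: float) -> tuple[float, float]:
    """Expected (IC1, IC2) means for a tissue with fraction rho altered."""
    b = baseline
    if alteration == "none" or rho == 0:
        return b, b
    if alteration == "cn_LOH":
        return b * (1 - rho) + rho, b * (1 - rho)
    if alteration == "epi_IC1":
        return b * (1 - rho) + rho, b
    if alteration == "epi_IC2":
        return b, b * (1 - rho)
    raise ValueError(
        f"no methylation mixture defined for alteration {alteration!r}; "
        f"expected one of {METHYLATION_ALTERATIONS}"
    )


def simulate_methylation(
    cfg: ScenarioConfig, sample_alterations=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MS-MLPA probe cohort around the imprinting mixture means.

    By default the cohort has ``n_altered`` samples carrying
    ``cfg.alteration`` at fraction ``rho`` followed by unaltered samples, up
    to ``n_samples``; ``sample_alterations`` overrides with an explicit
    per-sample list.  Probe values are the mixture mean plus Gaussian noise
    truncated to [0, 1].  Returns the long probe table and a truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    if sample_alterations is None:
        sample_alterations = [cfg.alteration] * cfg.n_altered + ["none"] * (
            cfg.n_samples - cfg.n_altered
        )
    rows, truth_rows = [], []
    for i, alteration in enumerate(sample_alterations):
        sid = f"S{i:03d}"
        rho = cfg.rho if alteration != "none" else 0.0
        ic1, ic2 = methylation_mixture_means(alteration, rho, cfg.ic_baseline)
        mean_of = {"IC1": ic1, "IC2": ic2, "IGF2_promoter": cfg.ic_baseline}
        for probe_id, target in MLPA_PROBES:
            value = np.clip(
                mean_of[target] + rng.normal(0.0, cfg.probe_noise_sd), 0.0, 1.0
            )
            rows.append(
                {"sample_id": sid, "probe_id": probe_id, "target": target, "value": value}
            )
        truth_rows.append(
            {"sample_id": sid, "alteration": alteration, "rho": rho,
             "ic1_true": ic1, "ic2_true": ic2}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_cells(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell allele counts at phased SNPs plus phasing and truth tables.

    Each cell is LOH with probability ``rho``; its read count is Poisson
    with mean ``reads_per_cell_mean``; each read falls on a uniformly chosen
    phased SNP and reports the paternal haplotype with probability
    ``1 - error_rate`` (LOH) or 0.5 (balanced).  Cell types are drawn from a
    fixed hepatic repertoire.  Returns (counts, phased, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    span = cfg.locus.end - cfg.locus.start + 1
    pos = np.sort(rng.choice(span, size=cfg.n_phased_snps, replace=False)) + cfg.locus.start
    pat_is_alt = rng.random(cfg.n_phased_snps) < 0.5
    phased = pd.DataFrame(
        {
            "chrom": cfg.locus.chrom,
            "pos": pos,
            "pat_allele": np.where(pat_is_alt, "alt", "ref"),
            "mat_allele": np.where(pat_is_alt, "ref", "alt"),
        }
    )
    cell_ids = np.array([f"C{i:05d}" for i in range(cfg.n_cells)])
    is_loh = rng.random(cfg.n_cells) < cfg.rho
    cell_type = rng.choice(
        ["hepatocyte", "cholangiocyte", "endothelial"], size=cfg.n_cells,
        p=[0.7, 0.15, 0.15],
    )
    n_reads = rng.poisson(cfg.reads_per_cell_mean, size=cfg.n_cells)
    cell_idx = np.repeat(np.arange(cfg.n_cells), n_reads)
    snp_idx = rng.integers(0, cfg.n_phased_snps, size=cell_idx.size)
    p_pat = np.where(is_loh[cell_idx], 1.0 - cfg.error_rate, 0.5)
    read_is_pat = rng.random(cell_idx.size) < p_pat
    allele = np.where(
        read_is_pat,
        phased["pat_allele"].to_numpy()[snp_idx],
        phased["mat_allele"].to_numpy()[snp_idx],
    )
    reads = pd.DataFrame(
        {
            "cell_id": cell_ids[cell_idx],
            "chrom": cfg.locus.chrom,
            "pos": pos[snp_idx],
            "allele": allele,
        }
    )
    counts = (
        reads.groupby(["cell_id", "chrom", "pos", "allele"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    truth = pd.DataFrame(
        {"cell_id": cell_ids, "is_loh": is_loh, "cell_type": cell_type, "n_reads": n_reads}
    )
    return counts, phased, truth


def simulate_junctions(
    cfg: ScenarioConfig, n_samples: int = 1
) -> tuple[list[JunctionCounts], dict]:
    """Multinomial junction category depths under a fixed usage vector.

    The universal-junction depth is fixed at ``cfg.universal_depth``.
    A zero ``junction_depth`` yields all-zero categories, flagged absent by
    the promoter-usage estimator downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(n_samples):
        draws = (
            rng.multinomial(cfg.junction_depth, cfg.usage_vector)
            if cfg.junction_depth > 0
            else np.zeros(4, dtype=int)
        )
        depths = dict(zip(CATEGORIES, (int(v) for v in draws)))
        out.append(JunctionCounts(depths, cfg.universal_depth, sample_id=f"S{i:03d}"))
    truth = {"usage_vector": dict(zip(CATEGORIES, cfg.usage_vector))}
    return out, truth
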