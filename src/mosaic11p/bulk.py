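"""Mosaic-fraction estimation from bulk SNP allele counts.

A somatic copy-number alteration present in a fraction rho of cells shifts
the B-allele frequency (BAF) of germline heterozygous SNPs inside the
altered locus away from 0.5.  For copy-neutral LOH (paternal uniparental
disomy, two major / zero minor alleles) the gained-allele dosage in the
mixed tissue is (1 + rho) / 2; for a paternal duplication (two major / one
minor) it is (1 + rho) / (2 + rho).  Inverting the general allele-dosage
relation gives the fraction of altered cells:

    % cells altered = 100 * (2*GAF - 1) / (GAF*(2 - Nmaj - Nmin) + Nmaj - 1)

where GAF is the median non-tumor BAF of the alleles gained in the matched
tumor, and (Nmaj, Nmin) are the major/minor allele copy numbers of the
alteration.  For cn-LOH this reduces to 100 * (2*GAF - 1).

Detection is a one-sided exact binomial test of the gained-allele read count
against a balanced p = 0.5, aggregated over all informative SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALTERATION_COPIES",
    "IMPRINTED_11P15",
    "LocusSpec",
    "MosaicEstimate",
    "NoInformativeSnpsError",
    "compute_baf",
    "prepare_sites",
    "orient_gained_alleles",
    "gained_allele_baf",
    "estimate_gaf",
    "mosaic_fraction_general",
    "mosaic_fraction_cnloh",
    "detect_mosaicism",
    "per_snp_pvalues",
    "area_fraction",
    "area_estimate",
    "BulkMosaicModel",
    "BulkMosaicResults",
]

#: (n_maj, n_min) allele copy numbers in fully altered cells.
ALTERATION_COPIES = {"cn_LOH": (2, 0), "paternal_dup": (2, 1)}

SNP_COLUMNS = ["chrom", "pos", "ref_nt", "alt_nt", "ref_t", "alt_t"]
#: Optional germline reference (e.g. blood) allele-depth columns.
GERMLINE_COLUMNS = ["ref_gl", "alt_gl"]


class NoInformativeSnpsError(ValueError):
    """No SNP survives the heterozygosity / orientation filters."""


@dataclass(frozen=True)
class LocusSpec:
    """A 1-based inclusive genomic interval carrying a copy-number alteration.

    Parameters
    ----------
    chrom, start, end
        Interval in 1-based inclusive coordinates.
    alteration
        ``"cn_LOH"`` (copy-neutral LOH, n_maj=2, n_min=0) or
        ``"paternal_dup"`` (n_maj=2, n_min=1).
    genome_build
        Free-text metadata; never interpreted.
    """

    chrom: str
    start: int
    end: int
    alteration: str = "cn_LOH"
    genome_build: str = ""

    def __post_init__(self) -> None:
        if self.alteration not in ALTERATION_COPIES:
            raise ValueError(
                f"unknown alteration {self.alteration!r}; "
                f"expected one of {sorted(ALTERATION_COPIES)}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError("locus requires 1 <= start <= end (1-based inclusive)")

    @property
    def n_maj(self) -> int:
        return ALTERATION_COPIES[self.alteration][0]

    @property
    def n_min(self) -> int:
        return ALTERATION_COPIES[self.alteration][1]


#: The telomeric imprinted region of chromosome 11p (IGF2/H19, CDKN1C/KCNQ1OT1).
IMPRINTED_11P15 = LocusSpec("chr11", 1, 2_800_000, "cn_LOH", genome_build="hg38")


@dataclass
class MosaicEstimate:
    """A mosaic-fraction estimate from one detection modality.

    ``fraction_pct`` is clamped to [0, 100]; the pre-clamp value is kept in
    ``raw_fraction_pct`` (sampling noise near rho=0 produces small negatives).
    """

    fraction_pct: float
    method: str  # one of {"baf", "methylation", "area", "sc"}
    gaf_nt: float = float("nan")
    n_snps: int = 0
    p_value: float = float("nan")
    detected: bool | None = None
    raw_fraction_pct: float = float("nan")
    sample_id: str = ""
    notes: list[str] = field(default_factory=list)


def compute_baf(ref_count, alt_count):
    """B-allele frequency alt/(ref+alt); NaN marks zero-depth (undefined).

    Accepts scalars or array-likes; negative counts are an input error.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("allele counts must be non-negative")
    depth = ref + alt
    baf = np.divide(alt, depth, out=np.full(np.broadcast(ref, alt).shape, np.nan), where=depth > 0)
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(baf)
    return baf


def prepare_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a SNP allele-count table and derive BAF columns.

    Requires columns ``chrom, pos, ref_nt, alt_nt, ref_t, alt_t``; adds
    ``baf_nt`` and ``baf_t`` (NaN where depth is zero).  Germline reference
    columns ``ref_gl, alt_gl`` are carried through and yield ``baf_gl``.
    """
    missing = [c for c in SNP_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    df = sites.copy()
    for col in SNP_COLUMNS[2:] + [c for c in GERMLINE_COLUMNS if c in df.columns]:
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    df["baf_nt"] = compute_baf(df["ref_nt"].to_numpy(), df["alt_nt"].to_numpy())
    df["baf_t"] = compute_baf(df["ref_t"].to_numpy(), df["alt_t"].to_numpy())
    if all(c in df.columns for c in GERMLINE_COLUMNS):
        df["baf_gl"] = compute_baf(df["ref_gl"].to_numpy(), df["alt_gl"].to_numpy())
    return df


def orient_gained_alleles(
    sites: pd.DataFrame,
    locus: LocusSpec | None = None,
    het_low: float = 0.2,
    het_high: float = 0.8,
    min_depth: int = 8,
    reference: str = "nt",
) -> pd.DataFrame:
    """Filter germline-heterozygous SNPs and orient them by the tumor BAF.

    The heterozygosity window [het_low, het_high] at depth >= min_depth is
    applied to the designated germline reference sample: ``reference="nt"``
    uses the non-tumor tissue itself (the default; biased when mosaicism is
    high), ``reference="germline"`` uses blood-like ``ref_gl/alt_gl``
    columns when present.  Sites with tumor BAF exactly 0.5 or undefined are
    dropped; the remainder get ``gained_is_alt`` = (tumor BAF > 0.5).
    """
    if not (0 < het_low < 0.5 < het_high < 1):
        raise ValueError("thresholds must satisfy 0 < het_low < 0.5 < het_high < 1")
    df = prepare_sites(sites)
    if locus is not None:
        df = df[(df["chrom"] == locus.chrom) & df["pos"].between(locus.start, locus.end)]
    if reference == "germline":
        if "baf_gl" not in df.columns:
            raise ValueError("reference='germline' requires ref_gl/alt_gl columns")
        ref_baf, ref_depth = df["baf_gl"], df["ref_gl"] + df["alt_gl"]
    elif reference == "nt":
        ref_baf, ref_depth = df["baf_nt"], df["ref_nt"] + df["alt_nt"]
    else:
        raise ValueError("reference must be 'nt' or 'germline'")
    het = (ref_depth >= min_depth) & ref_baf.between(het_low, het_high)
    informative = het & df["baf_t"].notna() & (df["baf_t"] != 0.5)
    out = df[informative].copy()
    out["gained_is_alt"] = out["baf_t"] > 0.5
    if out.empty:
        warnings.warn("no informative SNPs after filtering", stacklevel=2)
    return out


def gained_allele_baf(oriented: pd.DataFrame) -> np.ndarray:
    """Non-tumor BAF of the gained allele at each oriented site."""
    return np.where(oriented["gained_is_alt"], oriented["baf_nt"], 1.0 - oriented["baf_nt"])


def estimate_gaf(oriented: pd.DataFrame) -> float:
    """Median non-tumor BAF of the gained alleles (GAF).

    Even-count median is the midpoint of the middle pair.
    """
    if len(oriented) == 0:
        raise NoInformativeSnpsError("cannot estimate GAF from an empty site list")
    return float(np.median(gained_allele_baf(oriented)))


def _clamp_pct(raw: float) -> float:
    if raw < 0.0 or raw > 100.0:
        warnings.warn(
            f"mosaic fraction {raw:.3f}% outside [0, 100]; clamped", stacklevel=3
        )
        return float(min(max(raw, 0.0), 100.0))
    return float(raw)


def mosaic_fraction_general(gaf: float, locus: LocusSpec) -> float:
    """Percentage of altered cells from the gained-allele frequency.

    100 * (2*gaf - 1) / (gaf*(2 - n_maj - n_min) + n_maj - 1), clamped to
    [0, 100] with a warning when outside.
    """
    if not (0.0 <= gaf <= 1.0):
        raise ValueError("gaf must lie in [0, 1]")
    n_maj, n_min = locus.n_maj, locus.n_min
    denom = gaf * (2 - n_maj - n_min) + n_maj - 1
    if denom <= 0:
        raise ValueError(f"degenerate allele configuration: denominator {denom} <= 0")
    return _clamp_pct(100.0 * (2.0 * gaf - 1.0) / denom)


def mosaic_fraction_cnloh(gaf: float) -> float:
    """cn-LOH special case (n_maj=2, n_min=0): 100 * (2*gaf - 1), clamped."""
    if not (0.0 <= gaf <= 1.0):
        raise ValueError("gaf must lie in [0, 1]")
    return _clamp_pct(100.0 * (2.0 * gaf - 1.0))


def per_snp_pvalues(oriented: pd.DataFrame) -> pd.Series:
    """One-sided exact binomial tail per SNP (gained reads vs depth, p=0.5)."""
    gained = np.where(oriented["gained_is_alt"], oriented["alt_nt"], oriented["ref_nt"])
    total = (oriented["ref_nt"] + oriented["alt_nt"]).to_numpy()
    p = stats.binom.sf(gained.astype(int) - 1, total.astype(int), 0.5)
    return pd.Series(p, index=oriented.index, name="p_snp")


def detect_mosaicism(
    oriented: pd.DataFrame, locus: LocusSpec, alpha: float = 0.05
) -> MosaicEstimate:
    """Aggregate gained-allele reads and test against a balanced 0.5.

    Sums gained and total non-tumor reads over oriented sites, computes the
    one-sided exact binomial tail P(X >= gained | total, 0.5), and returns a
    :class:`MosaicEstimate` with the GAF-derived fraction.  Detection is
    positive when p < alpha.
    """
    if len(oriented) == 0:
        raise NoInformativeSnpsError("cannot test an empty site list")
    gained = np.where(oriented["gained_is_alt"], oriented["alt_nt"], oriented["ref_nt"])
    total = (oriented["ref_nt"] + oriented["alt_nt"]).to_numpy()
    k, n = int(gained.sum()), int(total.sum())
    p_value = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    gaf = estimate_gaf(oriented)
    raw = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fraction = mosaic_fraction_general(gaf, locus)
        notes = [str(w.message) for w in caught]
    n_maj, n_min = locus.n_maj, locus.n_min
    raw = 100.0 * (2.0 * gaf - 1.0) / (gaf * (2 - n_maj - n_min) + n_maj - 1)
    return MosaicEstimate(
        fraction_pct=fraction,
        method="baf",
        gaf_nt=gaf,
        n_snps=int(len(oriented)),
        p_value=p_value,
        detected=bool(p_value < alpha),
        raw_fraction_pct=raw,
        notes=notes,
    )


def area_fraction(mosaic_area: float, total_area: float) -> float:
    """Percentage of mosaic cells from annotated section areas."""
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if not (0 <= mosaic_area <= total_area):
        raise ValueError("mosaic_area must lie in [0, total_area]")
    return 100.0 * mosaic_area / total_area


def area_estimate(mosaic_area: float, total_area: float, sample_id: str = "") -> MosaicEstimate:
    """Area-based :class:`MosaicEstimate` (no p-value attached)."""
    pct = area_fraction(mosaic_area, total_area)
    return MosaicEstimate(
        fraction_pct=pct, method="area", raw_fraction_pct=pct, sample_id=sample_id
    )


class BulkMosaicModel:
    """Tumor-guided mosaicism model for a matched non-tumor/tumor SNP table.

    Parameters
    ----------
    sites
        DataFrame with ``chrom, pos, ref_nt, alt_nt, ref_t, alt_t`` and
        optionally germline reference columns ``ref_gl, alt_gl``.
    locus
        Altered interval with its alteration type; default is the 11p15.5
        imprinted region under cn-LOH.
    het_low, het_high, min_depth
        Heterozygosity filter applied to the reference sample.
    reference
        ``"nt"`` (filter on the non-tumor tissue itself), ``"germline"``
        (blood-like columns), or ``"auto"`` (germline when present).
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        locus: LocusSpec = IMPRINTED_11P15,
        het_low: float = 0.2,
        het_high: float = 0.8,
        min_depth: int = 8,
        reference: str = "auto",
    ) -> None:
        if reference == "auto":
            reference = "germline" if all(c in sites.columns for c in GERMLINE_COLUMNS) else "nt"
        self.locus = locus
        self.het_low = het_low
        self.het_high = het_high
        self.min_depth = min_depth
        self.reference = reference
        self.data = prepare_sites(sites)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "BulkMosaicModel":
        from .io import read_snp_tsv

        return cls(read_snp_tsv(path), **kwargs)

    @classmethod
    def from_vcf(cls, path, normal_sample=None, tumor_sample=None, germline_sample=None, **kwargs):
        from .io import read_vcf_pair

        sites = read_vcf_pair(
            path,
            normal_sample=normal_sample,
            tumor_sample=tumor_sample,
            germline_sample=germline_sample,
        )
        return cls(sites, **kwargs)

    def fit(self, alpha: float = 0.05) -> "BulkMosaicResults":
        oriented = orient_gained_alleles(
            self.data,
            self.locus,
            het_low=self.het_low,
            het_high=self.het_high,
            min_depth=self.min_depth,
            reference=self.reference,
        )
        estimate = detect_mosaicism(oriented, self.locus, alpha=alpha)
        if self.reference == "nt" and estimate.fraction_pct > 40.0:
            msg = (
                "heterozygosity filter used the non-tumor sample itself and the "
                "estimated fraction exceeds 40%: high mosaicism shifts the BAF and "
                "biases the filter; prefer a blood/germline reference"
            )
            warnings.warn(msg, stacklevel=2)
            estimate.notes.append(msg)
        oriented = oriented.assign(p_snp=per_snp_pvalues(oriented))
        return BulkMosaicResults(self, estimate, oriented, alpha)


class BulkMosaicResults:
    """Estimates and diagnostics from :meth:`BulkMosaicModel.fit`."""

    def __init__(self, model, estimate, oriented, alpha):
        self.model = model
        self.estimate = estimate
        self.oriented_sites = oriented
        self.alpha = alpha

    @property
    def fraction_pct(self) -> float:
        return self.estimate.fraction_pct

    @property
    def gaf_nt(self) -> float:
        return self.estimate.gaf_nt

    @property
    def p_value(self) -> float:
        return self.estimate.p_value

    @property
    def detected(self) -> bool:
        return bool(self.estimate.detected)

    def to_frame(self) -> pd.DataFrame:
        e = self.estimate
        return pd.DataFrame(
            [
                {
                    "chrom": self.model.locus.chrom,
                    "start": self.model.locus.start,
                    "end": self.model.locus.end,
                    "alteration": self.model.locus.alteration,
                    "gaf_nt": e.gaf_nt,
                    "fraction_pct": e.fraction_pct,
                    "n_snps": e.n_snps,
                    "p_value": e.p_value,
                    "detected": e.detected,
                }
            ]
        )

    def summary(self) -> str:
        e = self.estimate
        loc = self.model.locus
        lines = [
            "Bulk BAF mosaicism estimate",
            "===========================",
            f"locus            {loc.chrom}:{loc.start}-{loc.end} ({loc.alteration})",
            f"informative SNPs {e.n_snps}",
            f"GAF (non-tumor)  {e.gaf_nt:.4f}",
            f"fraction altered {e.fraction_pct:.2f} %",
            f"binomial p-value {e.p_value:.3g}",
            f"detected (a={self.alpha:g}) {e.detected}",
        ]
        for note in e.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)
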