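"""Imprinting-center methylation analysis (MS-MLPA probes and RRBS CpGs).

IC1 (paternally methylated, controls IGF2/H19) and IC2 (maternally
methylated, controls KCNQ1OT1/CDKN1C) are balanced near a common baseline in
normal tissue, so the IC1/IC2 ratio is ~1.  Paternal uniparental disomy
raises IC1 and lowers IC2 symmetrically; the fraction of altered cells then
follows

    % cells altered = 100 * (IC1 - IC2) / (IC1 + IC2)

Epimutations (gain of methylation at IC1, loss at IC2) are called per sample
from per-probe two-cluster k-means thresholds across a cohort, requiring at
least 2 of 3 usable IC1 probes (respectively 2 of 4 IC2 probes) beyond their
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bulk import _clamp_pct

__all__ = [
    "EXCLUDED_PROBES",
    "DEFAULT_IC_REGIONS",
    "PromoterRegion",
    "usable_probes",
    "ic_means",
    "ic_ratio",
    "mosaic_fraction_methylation",
    "kmeans_threshold",
    "classify_epimutation",
    "rrbs_region_methylation",
    "classify_mosaic_by_ratio",
    "MethylationModel",
    "MethylationResults",
]

#: Probes excluded from analysis; this IC1 probe does not discriminate
#: samples with and without gain of methylation.
EXCLUDED_PROBES = frozenset({"H19.11.001.976583"})

MLPA_COLUMNS = ["sample_id", "probe_id", "target", "value"]
RRBS_COLUMNS = ["chrom", "pos", "meth_count", "unmeth_count"]


@dataclass(frozen=True)
class PromoterRegion:
    """A named 1-based inclusive region (IGF2 promoter or imprinting center)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region requires start <= end")


#: hg38 imprinting-center intervals used for RRBS region means.
DEFAULT_IC_REGIONS = {
    "IC1": PromoterRegion("IC1", "chr11", 1_998_745, 2_003_509),
    "IC2": PromoterRegion("IC2", "chr11", 2_697_587, 2_700_983),
}


def usable_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Drop probes excluded by flag or by the default exclusion list."""
    df = probes.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool) | df["probe_id"].isin(EXCLUDED_PROBES)
    return df[~df["excluded"]].drop(columns="excluded")


def ic_means(probes: pd.DataFrame) -> tuple[float, float]:
    """Mean methylation of non-excluded IC1 and IC2 probes for one sample."""
    df = usable_probes(probes)
    out = []
    for target in ("IC1", "IC2"):
        vals = df.loc[df["target"] == target, "value"]
        if vals.empty:
            raise ValueError(f"no usable {target} probes")
        out.append(float(vals.mean()))
    return out[0], out[1]


def ic_ratio(ic1_mean: float, ic2_mean: float) -> float:
    """IC1/IC2 methylation ratio; ~1 in non-mosaic tissue."""
    if ic2_mean <= 0:
        raise ValueError("ic_ratio requires ic2_mean > 0")
    return ic1_mean / ic2_mean


def mosaic_fraction_methylation(ic1_mean: float, ic2_mean: float) -> float:
    """Percentage of altered cells from IC means: 100*(IC1-IC2)/(IC1+IC2).

    Clamped to [0, 100]; negative values (IC2 > IC1, e.g. maternal UPD or
    noise) trigger a warning before clamping.
    """
    total = ic1_mean + ic2_mean
    if total <= 0:
        raise ValueError("requires ic1_mean + ic2_mean > 0")
    return _clamp_pct(100.0 * (ic1_mean - ic2_mean) / total)


def kmeans_threshold(values) -> float | None:
    """Exact two-cluster 1-D k-means threshold (midpoint of the two means).

    In one dimension the globally optimal 2-means partition is always a
    contiguous split of the sorted values, so the optimum is found by
    scanning all n-1 splits for the minimal within-cluster sum of squares.
    Deterministic; ties resolve to the lowest split.  Returns None for
    degenerate input (fewer than two distinct values).
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[~np.isnan(x)])
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return None
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    k = np.arange(1, n)  # left-cluster sizes
    left_mean = csum[:-1] / k
    right_mean = (csum[-1] - csum[:-1]) / (n - k)
    within = (
        csum2[:-1] - k * left_mean**2
        + (csum2[-1] - csum2[:-1]) - (n - k) * right_mean**2
    )
    best = int(np.argmin(within))
    return float((left_mean[best] + right_mean[best]) / 2.0)


def classify_epimutation(cohort: pd.DataFrame, min_hits: int = 2) -> pd.DataFrame:
    """Call GOM-IC1 / LOM-IC2 epimutations across a cohort.

    ``cohort`` is a long table (sample_id, probe_id, target, value).  Each
    usable probe gets a two-cluster k-means threshold across samples; a
    sample is GOM-IC1 when >= ``min_hits`` IC1 probes lie above their
    thresholds, and LOM-IC2 when >= ``min_hits`` IC2 probes lie below theirs
    (loss direction).  Probes without a threshold (degenerate distribution)
    never count as hits.

    Returns a boolean DataFrame indexed by sample_id with columns
    ``gom_ic1`` and ``lom_ic2``.
    """
    df = usable_probes(cohort)
    samples = df["sample_id"].unique()
    if len(samples) < 2:
        raise ValueError("epimutation classification requires >= 2 samples")
    wide = df.pivot_table(index="sample_id", columns="probe_id", values="value")
    target_of = df.drop_duplicates("probe_id").set_index("probe_id")["target"]
    thresholds: dict[str, float | None] = {
        p: kmeans_threshold(wide[p].to_numpy()) for p in wide.columns
    }
    degenerate = [p for p, t in thresholds.items() if t is None]
    if degenerate:
        warnings.warn(
            f"degenerate probe distribution(s), no threshold: {degenerate}",
            stacklevel=2,
        )
    gom_hits = pd.Series(0, index=wide.index)
    lom_hits = pd.Series(0, index=wide.index)
    for probe, thr in thresholds.items():
        if thr is None:
            continue
        if target_of[probe] == "IC1":
            gom_hits += (wide[probe] > thr).astype(int)
        elif target_of[probe] == "IC2":
            lom_hits += (wide[probe] < thr).astype(int)
    return pd.DataFrame(
        {"gom_ic1": gom_hits >= min_hits, "lom_ic2": lom_hits >= min_hits},
        index=wide.index,
    )


def rrbs_region_methylation(
    cpgs: pd.DataFrame, region: PromoterRegion, exclude_positions=None
) -> float | None:
    """Pooled-count methylation of a region: sum(meth) / sum(meth + unmeth).

    Uses pooled cytosine counts over in-region CpGs, not the mean of per-CpG
    ratios, so deep CpGs weigh more.  ``exclude_positions`` removes known
    biased CpG sites.  Returns None when no covered CpG falls in the region.
    """
    missing = [c for c in RRBS_COLUMNS if c not in cpgs.columns]
    if missing:
        raise ValueError(f"RRBS table missing columns: {missing}")
    if (cpgs[["meth_count", "unmeth_count"]] < 0).any().any():
        raise ValueError("negative CpG counts")
    mask = (cpgs["chrom"] == region.chrom) & cpgs["pos"].between(region.start, region.end)
    if exclude_positions is not None:
        mask &= ~cpgs["pos"].isin(set(exclude_positions))
    sub = cpgs[mask]
    meth = int(sub["meth_count"].sum())
    total = meth + int(sub["unmeth_count"].sum())
    if total == 0:
        return None
    return meth / total


def classify_mosaic_by_ratio(ratio: float, cohort_ratios, k_sd: float = 3.0) -> bool:
    """Flag a sample whose IC1/IC2 ratio is an outlier against normals.

    True when the ratio lies strictly beyond mean +/- k_sd * SD of the
    presumed-normal cohort (both directions: LOM-IC2 raises the ratio,
    maternal-side anomalies lower it).
    """
    arr = np.asarray(cohort_ratios, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("normal cohort has zero SD")
    return bool(abs(ratio - mean) > k_sd * sd)


class MethylationModel:
    """Per-sample imprinting-center methylation model for an MS-MLPA cohort.

    Parameters
    ----------
    probes
        Long table (sample_id, probe_id, target, value); targets are IC1,
        IC2 or IGF2_promoter.
    normal_ratios
        Optional IC1/IC2 ratios of presumed-normal samples, enabling the
        outlier-based mosaic flag.
    k_sd
        SD multiplier for the ratio outlier rule.
    """

    def __init__(self, probes: pd.DataFrame, normal_ratios=None, k_sd: float = 3.0):
        missing = [c for c in MLPA_COLUMNS if c not in probes.columns]
        if missing:
            raise ValueError(f"MS-MLPA table missing columns: {missing}")
        bad = ~probes["value"].between(0, 1)
        if bad.any():
            raise ValueError("probe methylation values must lie in [0, 1]")
        self.probes = probes.copy()
        self.normal_ratios = None if normal_ratios is None else np.asarray(normal_ratios, float)
        self.k_sd = k_sd

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "MethylationModel":
        from .io import read_mlpa_tsv

        return cls(read_mlpa_tsv(path), **kwargs)

    def fit(self) -> "MethylationResults":
        rows = []
        sample_ids = list(pd.unique(self.probes["sample_id"]))
        if len(sample_ids) >= 2:
            epi = classify_epimutation(self.probes)
        else:
            epi = None
        for sid in sample_ids:
            sub = self.probes[self.probes["sample_id"] == sid]
            ic1, ic2 = ic_means(sub)
            ratio = ic_ratio(ic1, ic2) if ic2 > 0 else np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frac = mosaic_fraction_methylation(ic1, ic2)
            row = {
                "sample_id": sid,
                "ic1_mean": ic1,
                "ic2_mean": ic2,
                "ratio": ratio,
                "fraction_pct": frac,
                "gom_ic1": bool(epi.loc[sid, "gom_ic1"]) if epi is not None else None,
                "lom_ic2": bool(epi.loc[sid, "lom_ic2"]) if epi is not None else None,
            }
            if self.normal_ratios is not None and np.isfinite(ratio):
                row["mosaic_flag"] = classify_mosaic_by_ratio(
                    ratio, self.normal_ratios, self.k_sd
                )
            else:
                row["mosaic_flag"] = None
            rows.append(row)
        return MethylationResults(self, pd.DataFrame(rows).set_index("sample_id"))


class MethylationResults:
    """Per-sample table from :meth:`MethylationModel.fit`."""

    def __init__(self, model: MethylationModel, samples: pd.DataFrame):
        self.model = model
        self.samples = samples

    def to_frame(self) -> pd.DataFrame:
        return self.samples.reset_index()

    def summary(self) -> str:
        lines = [
            "Imprinting-center methylation summary",
            "=====================================",
            f"samples: {len(self.samples)}",
        ]
        with pd.option_context("display.width", 120):
            lines.append(
                self.samples[["ic1_mean", "ic2_mean", "ratio", "fraction_pct"]]
                .round(4)
                .to_string()
            )
        return "\n".join(lines)
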