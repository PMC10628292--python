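"""Single-nucleus genotyping of 11p15.5 copy-neutral LOH.

Germline heterozygous SNPs inside the altered locus are phased against the
matched bulk tumor, where the cn-LOH produces a strong allelic
disequilibrium: the majority tumor allele is the duplicated paternal (PAT)
haplotype, the minority allele the lost maternal (MAT) haplotype.  Reads in
each nucleus are then summed per haplotype, the per-cell BAF is
PAT / (PAT + MAT), and cells with at least 8 informative reads are called
cn-LOH when BAF >= 0.85, no-cn-LOH when BAF <= 0.60, and unknown otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bulk import LocusSpec, NoInformativeSnpsError, orient_gained_alleles

__all__ = [
    "assign_parental_alleles",
    "aggregate_cell_counts",
    "call_cell",
    "call_cells",
    "annotate_reference_sample",
    "summarize_by_celltype",
    "SingleCellLohModel",
    "SingleCellLohResults",
]

PHASED_COLUMNS = ["chrom", "pos", "pat_allele", "mat_allele"]
COUNT_COLUMNS = ["cell_id", "chrom", "pos", "allele", "count"]


def assign_parental_alleles(
    sites: pd.DataFrame,
    locus: LocusSpec | None = None,
    het_low: float = 0.2,
    het_high: float = 0.8,
    min_depth: int = 8,
    reference: str = "nt",
) -> pd.DataFrame:
    """Phase heterozygous SNPs by the tumor allelic disequilibrium.

    Non-tumor BAFs filter out germline homozygous SNPs (same window as the
    bulk detector); the majority tumor allele becomes PAT (duplicated), the
    other MAT (lost).  Returns (chrom, pos, pat_allele, mat_allele) with
    alleles labelled "ref"/"alt".
    """
    oriented = orient_gained_alleles(
        sites, locus, het_low=het_low, het_high=het_high,
        min_depth=min_depth, reference=reference,
    )
    if oriented.empty:
        raise NoInformativeSnpsError("no phasable SNPs")
    pat = np.where(oriented["gained_is_alt"], "alt", "ref")
    mat = np.where(oriented["gained_is_alt"], "ref", "alt")
    return pd.DataFrame(
        {"chrom": oriented["chrom"].to_numpy(), "pos": oriented["pos"].to_numpy(),
         "pat_allele": pat, "mat_allele": mat}
    )


def aggregate_cell_counts(
    counts: pd.DataFrame, phased: pd.DataFrame, cell_types: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sum PAT and MAT reads per cell over phased SNPs.

    ``counts`` is a long table (cell_id, chrom, pos, allele, count);
    ``phased`` maps each SNP to its PAT/MAT allele labels.  Reads at SNPs
    absent from the phasing, or at alleles matching neither haplotype, are
    ignored; cells left without any informative read are omitted with a
    warning.  ``cell_types`` (cell_id, cell_type) is merged when given.
    """
    for cols, df, name in ((COUNT_COLUMNS, counts, "count"), (PHASED_COLUMNS, phased, "phased")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("negative read counts")
    merged = counts.merge(phased, on=["chrom", "pos"], how="inner")
    is_pat = merged["allele"] == merged["pat_allele"]
    is_mat = merged["allele"] == merged["mat_allele"]
    pat = merged.loc[is_pat].groupby("cell_id")["count"].sum()
    mat = merged.loc[is_mat].groupby("cell_id")["count"].sum()
    cells = pd.DataFrame({"pat_reads": pat, "mat_reads": mat}).fillna(0).astype(int)
    dropped = set(counts["cell_id"].unique()) - set(cells.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} cell(s) without informative reads omitted", stacklevel=2
        )
    total = cells["pat_reads"] + cells["mat_reads"]
    cells["baf_cell"] = np.where(total > 0, cells["pat_reads"] / total.replace(0, 1), np.nan)
    cells = cells.reset_index()
    if cell_types is not None:
        cells = cells.merge(cell_types[["cell_id", "cell_type"]], on="cell_id", how="left")
    return cells


def call_cell(
    pat_reads: int,
    mat_reads: int,
    min_reads: int = 8,
    loh_baf: float = 0.85,
    ref_baf: float = 0.60,
) -> str:
    """Three-way cn-LOH call for one cell from its haplotype read counts.

    unknown below ``min_reads`` informative reads; cn_LOH when
    BAF >= ``loh_baf`` (inclusive); no_cnLOH when BAF <= ``ref_baf``
    (inclusive); unknown in between.
    """
    if ref_baf >= loh_baf:
        raise ValueError("thresholds must satisfy ref_baf < loh_baf")
    total = pat_reads + mat_reads
    if total < min_reads:
        return "unknown"
    baf = pat_reads / total
    if baf >= loh_baf:
        return "cn_LOH"
    if baf <= ref_baf:
        return "no_cnLOH"
    return "unknown"


def call_cells(
    cells: pd.DataFrame,
    min_reads: int = 8,
    loh_baf: float = 0.85,
    ref_baf: float = 0.60,
) -> pd.DataFrame:
    """Vectorized :func:`call_cell` over an aggregated cell table."""
    if ref_baf >= loh_baf:
        raise ValueError("thresholds must satisfy ref_baf < loh_baf")
    total = cells["pat_reads"] + cells["mat_reads"]
    baf = np.where(total > 0, cells["pat_reads"] / total.replace(0, 1), np.nan)
    call = np.full(len(cells), "unknown", dtype=object)
    enough = total >= min_reads
    call[enough & (baf >= loh_baf)] = "cn_LOH"
    call[enough & (baf <= ref_baf)] = "no_cnLOH"
    return cells.assign(call=call)


def annotate_reference_sample(
    cells: pd.DataFrame, sample_is_altered: bool, **call_kwargs
) -> pd.DataFrame:
    """Call cells, overriding to no_cnLOH for a sample whose tumor had no cn-LOH.

    Cells from a patient without any cn-LOH in the tumor are reference
    negatives regardless of their read counts.
    """
    if not sample_is_altered:
        return cells.assign(call="no_cnLOH")
    return call_cells(cells, **call_kwargs)


def summarize_by_celltype(cells_with_calls: pd.DataFrame) -> pd.DataFrame:
    """Per cell-type summary: n cells, mean BAF, calls, cn-LOH fraction.

    The cn-LOH fraction is computed over determinate calls only
    (cn_LOH / (cn_LOH + no_cnLOH)); 0.0 when every call is unknown.
    Unknown counts are always reported.
    """
    if "cell_type" not in cells_with_calls.columns:
        raise ValueError("cell_type column required")
    rows = []
    for ctype, grp in cells_with_calls.groupby("cell_type", sort=True):
        n_loh = int((grp["call"] == "cn_LOH").sum())
        n_no = int((grp["call"] == "no_cnLOH").sum())
        n_unknown = int((grp["call"] == "unknown").sum())
        determinate = n_loh + n_no
        rows.append(
            {
                "cell_type": ctype,
                "n_cells": int(len(grp)),
                "mean_baf": float(grp["baf_cell"].mean()) if grp["baf_cell"].notna().any() else np.nan,
                "n_cnLOH": n_loh,
                "n_no_cnLOH": n_no,
                "n_unknown": n_unknown,
                "cnLOH_fraction": n_loh / determinate if determinate > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


class SingleCellLohModel:
    """Per-nucleus cn-LOH genotyping model.

    Parameters
    ----------
    counts
        Long per-cell allele-count table (cell_id, chrom, pos, allele, count).
    phased
        Phased SNP table (chrom, pos, pat_allele, mat_allele), e.g. from
        :func:`assign_parental_alleles`.
    cell_types
        Optional (cell_id, cell_type) labels.
    sample_is_altered
        False for a patient whose tumor carries no cn-LOH: every cell is
        then a reference negative.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        phased: pd.DataFrame,
        cell_types: pd.DataFrame | None = None,
        sample_is_altered: bool = True,
        min_reads: int = 8,
        loh_baf: float = 0.85,
        ref_baf: float = 0.60,
    ):
        self.counts = counts
        self.phased = phased
        self.cell_types = cell_types
        self.sample_is_altered = sample_is_altered
        self.min_reads = min_reads
        self.loh_baf = loh_baf
        self.ref_baf = ref_baf

    def fit(self) -> "SingleCellLohResults":
        cells = aggregate_cell_counts(self.counts, self.phased, self.cell_types)
        called = annotate_reference_sample(
            cells,
            self.sample_is_altered,
            min_reads=self.min_reads,
            loh_baf=self.loh_baf,
            ref_baf=self.ref_baf,
        )
        by_type = (
            summarize_by_celltype(called) if "cell_type" in called.columns else None
        )
        return SingleCellLohResults(self, called, by_type)


class SingleCellLohResults:
    """Per-cell calls and per-type summary from :meth:`SingleCellLohModel.fit`."""

    def __init__(self, model, cells, by_type):
        self.model = model
        self.cells = cells
        self.by_type = by_type

    def to_frame(self) -> pd.DataFrame:
        return self.cells

    def summary(self) -> str:
        n = len(self.cells)
        counts = self.cells["call"].value_counts().to_dict()
        lines = [
            "Single-nucleus cn-LOH calls",
            "===========================",
            f"cells            {n}",
            f"cn_LOH           {counts.get('cn_LOH', 0)}",
            f"no_cnLOH         {counts.get('no_cnLOH', 0)}",
            f"unknown          {counts.get('unknown', 0)}",
            f"thresholds       min_reads={self.model.min_reads}, "
            f"loh_baf={self.model.loh_baf}, ref_baf={self.model.ref_baf}",
        ]
        if self.by_type is not None:
            lines.append(self.by_type.round(4).to_string(index=False))
        return "\n".join(lines)
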