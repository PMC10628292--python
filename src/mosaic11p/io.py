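"""Readers, writers and structured logging for the pipeline's table formats.

All genomic coordinates are 1-based inclusive internally; BED input
(0-based half-open) is converted on read.  TSVs are UTF-8, tab-delimited,
with a mandatory header row; missing values are written as empty strings.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .bulk import SNP_COLUMNS
from .methylation import MLPA_COLUMNS, RRBS_COLUMNS, PromoterRegion
from .sc import COUNT_COLUMNS, PHASED_COLUMNS

__all__ = [
    "read_snp_tsv",
    "read_vcf_pair",
    "read_bed_regions",
    "read_mlpa_tsv",
    "read_rrbs_tsv",
    "read_cell_counts_tsv",
    "read_celltype_tsv",
    "read_phased_tsv",
    "read_junction_tsv",
    "write_tsv",
    "RunLog",
]


def _read_table(path, required, count_columns=(), dtype_int=()):
    """Tab-separated read with column validation and row-level count checks.

    Malformed rows (negative counts, non-numeric values) are rejected with
    1-based data line numbers.  An empty file yields an empty table with the
    required columns and a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str} if "chrom" in required else None)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file", stacklevel=3)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in count_columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:10]
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        neg = vals < 0
        if neg.any():
            lines = (df.index[neg] + 2).tolist()[:10]
            raise ValueError(f"{path}: negative {col!r} at line(s) {lines}")
        df[col] = vals
    for col in dtype_int:
        df[col] = df[col].astype(int)
    return df


def read_snp_tsv(path) -> pd.DataFrame:
    """SNP allele-count table (chrom, pos, ref_nt, alt_nt, ref_t, alt_t
    [, ref_gl, alt_gl])."""
    count_cols = SNP_COLUMNS[2:]
    df = _read_table(path, SNP_COLUMNS, count_columns=count_cols)
    extra = [c for c in ("ref_gl", "alt_gl") if c in df.columns]
    for col in extra:
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative {col!r}")
    if len(df):
        df = df.astype({c: int for c in ["pos"] + count_cols + extra})
    return df


def read_vcf_pair(
    path,
    normal_sample: str | None = None,
    tumor_sample: str | None = None,
    germline_sample: str | None = None,
) -> pd.DataFrame:
    """Build a SNP allele-count table from a VCF with per-sample AD fields.

    ``normal_sample`` / ``tumor_sample`` default to the first and second
    sample columns.  Multi-allelic records are skipped with a warning; a
    missing AD field is an error.  Coordinates are preserved exactly
    (VCF POS is already 1-based).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if normal_sample is None:
        normal_sample = samples[0]
    if tumor_sample is None:
        if len(samples) < 2:
            raise ValueError(
                f"{path}: single-sample VCF; tumor_sample must name a sample"
            )
        tumor_sample = samples[1]
    idx = {}
    for role, name in (
        ("nt", normal_sample),
        ("t", tumor_sample),
        ("gl", germline_sample),
    ):
        if name is None:
            continue
        if name not in samples:
            raise ValueError(f"{path}: sample {name!r} not in VCF ({samples})")
        idx[role] = samples.index(name)
    rows = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"{path}: missing allele-depth (AD) field at "
                             f"{variant.CHROM}:{variant.POS}")
        row = {"chrom": variant.CHROM, "pos": variant.POS}
        for role, i in idx.items():
            ref, alt = int(ad[i][0]), int(ad[i][1])
            row[f"ref_{role}"], row[f"alt_{role}"] = max(ref, 0), max(alt, 0)
        rows.append(row)
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multi-allelic record(s)", stacklevel=2)
    if not rows:
        warnings.warn(f"{path}: no usable variants", stacklevel=2)
        cols = SNP_COLUMNS + (["ref_gl", "alt_gl"] if "gl" in idx else [])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def read_bed_regions(path) -> list[PromoterRegion]:
    """Named regions from BED (0-based half-open -> 1-based inclusive)."""
    regions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            chrom, start, end, name = fields[:4]
            regions.append(PromoterRegion(name, chrom, int(start) + 1, int(end)))
    return regions


def read_mlpa_tsv(path) -> pd.DataFrame:
    """MS-MLPA probe table (sample_id, probe_id, target, value)."""
    df = _read_table(path, MLPA_COLUMNS, count_columns=())
    if len(df) and not df["value"].between(0, 1).all():
        raise ValueError(f"{path}: probe values must lie in [0, 1]")
    return df


def read_rrbs_tsv(path) -> pd.DataFrame:
    """RRBS per-CpG table (chrom, pos, meth_count, unmeth_count)."""
    df = _read_table(
        path, RRBS_COLUMNS, count_columns=["pos", "meth_count", "unmeth_count"]
    )
    if len(df):
        df = df.astype({"pos": int, "meth_count": int, "unmeth_count": int})
    return df


def read_cell_counts_tsv(path) -> pd.DataFrame:
    """Per-cell allele counts (cell_id, chrom, pos, allele, count)."""
    df = _read_table(path, COUNT_COLUMNS, count_columns=["pos", "count"])
    if len(df):
        df = df.astype({"pos": int, "count": int})
    return df


def read_celltype_tsv(path) -> pd.DataFrame:
    """Cell-type labels (cell_id, cell_type); labels are free text."""
    return _read_table(path, ["cell_id", "cell_type"])


def read_phased_tsv(path) -> pd.DataFrame:
    """Phased SNPs (chrom, pos, pat_allele, mat_allele)."""
    df = _read_table(path, PHASED_COLUMNS, count_columns=["pos"])
    if len(df):
        df = df.astype({"pos": int})
    return df


def read_junction_tsv(path) -> pd.DataFrame:
    """Splice-junction depths (sample_id, junction_id, depth)."""
    df = _read_table(path, ["sample_id", "junction_id", "depth"], count_columns=["depth"])
    if len(df):
        df = df.astype({"depth": int})
    return df


def write_tsv(df: pd.DataFrame, path) -> Path:
    """UTF-8 tab-delimited write; missing values as empty strings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


class RunLog:
    """Structured key=value logging with a stable line schema.

    Each :meth:`write` call emits one line of space-separated ``key=value``
    pairs in the order given, so tests and downstream tooling can parse it.
    """

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text("", encoding="utf-8")

    @staticmethod
    def _format(value) -> str:
        if isinstance(value, float):
            return f"{value:.6g}"
        return str(value)

    def write(self, **fields) -> str:
        line = " ".join(f"{k}={self._format(v)}" for k, v in fields.items())
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(line + "\n")
        return line
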