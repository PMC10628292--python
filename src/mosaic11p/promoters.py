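"""IGF2 promoter-usage quantification from splice-junction depths.

IGF2 is transcribed from the adult liver-specific promoters P0-P1 and the
fetal promoters P2, P3, P4.  Each promoter category is summarized by the
maximum depth over its category-specific splice junctions; depths are
normalized by the depth of "universal" junctions shared by all transcripts
(comparable across samples), and proportions of promoter usage are the
normalized values divided by their sum.  The fetal fraction is the summed
proportion of P2 + P3 + P4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CATEGORIES",
    "FETAL_CATEGORIES",
    "JunctionCounts",
    "PromoterUsage",
    "normalize_junctions",
    "promoter_usage",
    "junction_table_to_counts",
    "PromoterUsageModel",
    "PromoterUsageResults",
]

CATEGORIES = ("P0-P1", "P2", "P3", "P4")
FETAL_CATEGORIES = ("P2", "P3", "P4")
UNIVERSAL = "universal"


@dataclass
class JunctionCounts:
    """Per-sample junction depths: one maximum per promoter category plus
    the universal-junction depth used for normalization."""

    category_depths: dict
    universal_depth: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.category_depths) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown promoter categories: {sorted(unknown)}")
        full = {c: int(self.category_depths.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in full.values()) or self.universal_depth < 0:
            raise ValueError("junction depths must be non-negative")
        self.category_depths = full


@dataclass
class PromoterUsage:
    """Promoter-usage proportions; ``absent`` when no category had signal."""

    proportions: dict | None
    fetal_fraction: float | None
    normalized: dict = field(default_factory=dict)
    sample_id: str = ""

    @property
    def absent(self) -> bool:
        return self.proportions is None


def normalize_junctions(jc: JunctionCounts) -> dict:
    """Category depths divided by the universal-junction depth."""
    if jc.universal_depth <= 0:
        raise ValueError("universal_depth must be positive for normalization")
    return {c: jc.category_depths[c] / jc.universal_depth for c in CATEGORIES}


def promoter_usage(jc: JunctionCounts) -> PromoterUsage:
    """Proportions of promoter usage from normalized junction depths.

    Within one sample the universal normalization cancels in the proportion;
    the normalized values are still emitted for cross-sample comparison of
    absolute promoter activity.  All-zero categories yield an absent usage.
    """
    normalized = normalize_junctions(jc)
    total = sum(normalized.values())
    if total == 0:
        warnings.warn(
            f"no junction signal in any promoter category"
            f"{' for ' + jc.sample_id if jc.sample_id else ''}",
            stacklevel=2,
        )
        return PromoterUsage(None, None, normalized, jc.sample_id)
    proportions = {c: normalized[c] / total for c in CATEGORIES}
    fetal = sum(proportions[c] for c in FETAL_CATEGORIES)
    return PromoterUsage(proportions, fetal, normalized, jc.sample_id)


def junction_table_to_counts(
    junctions: pd.DataFrame, category_map: dict
) -> list[JunctionCounts]:
    """Summarize a long junction table into per-sample category maxima.

    ``junctions`` has columns (sample_id, junction_id, depth); ``category_map``
    maps junction_id to a promoter category or to ``"universal"``.  The depth
    of a category is the maximum over its junctions; the universal depth is
    the maximum over universal junctions.
    """
    required = ["sample_id", "junction_id", "depth"]
    missing = [c for c in required if c not in junctions.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")
    bad = sorted(set(category_map.values()) - set(CATEGORIES) - {UNIVERSAL})
    if bad:
        raise ValueError(f"category map contains unknown categories: {bad}")
    df = junctions.copy()
    df["category"] = df["junction_id"].map(category_map)
    unmapped = df["category"].isna()
    if unmapped.any():
        warnings.warn(
            f"{int(unmapped.sum())} junction row(s) absent from the category map ignored",
            stacklevel=2,
        )
        df = df[~unmapped]
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        maxima = grp.groupby("category")["depth"].max()
        universal = int(maxima.get(UNIVERSAL, 0))
        depths = {c: int(maxima.get(c, 0)) for c in CATEGORIES}
        out.append(JunctionCounts(depths, universal, sample_id=str(sid)))
    return out


class PromoterUsageModel:
    """Promoter-usage model over one or more samples.

    Accepts either pre-summarized :class:`JunctionCounts` or a long junction
    table plus a junction-to-category map.
    """

    def __init__(self, counts: list[JunctionCounts]):
        self.counts = list(counts)

    @classmethod
    def from_junction_table(cls, junctions: pd.DataFrame, category_map: dict):
        return cls(junction_table_to_counts(junctions, category_map))

    @classmethod
    def from_summary_frame(cls, df: pd.DataFrame) -> "PromoterUsageModel":
        """Build from a table (sample_id, category, max_depth, universal_depth)."""
        counts = []
        for sid, grp in df.groupby("sample_id", sort=True):
            depths = dict(zip(grp["category"], grp["max_depth"].astype(int)))
            universal = int(grp["universal_depth"].iloc[0])
            counts.append(JunctionCounts(depths, universal, sample_id=str(sid)))
        return cls(counts)

    def fit(self) -> "PromoterUsageResults":
        usages = [promoter_usage(jc) for jc in self.counts]
        return PromoterUsageResults(self, usages)


class PromoterUsageResults:
    """Per-sample promoter-usage proportions."""

    def __init__(self, model, usages: list[PromoterUsage]):
        self.model = model
        self.usages = usages

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.usages:
            row = {"sample_id": u.sample_id}
            for c in CATEGORIES:
                row[c] = u.proportions[c] if u.proportions else float("nan")
            row["fetal_fraction"] = u.fetal_fraction if u.fetal_fraction is not None else float("nan")
            row["absent"] = u.absent
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["IGF2 promoter usage", "==================="]
        lines.append(self.to_frame().round(4).to_string(index=False))
        return "\n".join(lines)
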