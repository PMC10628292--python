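import numpy as np
import pandas as pd
import pytest

from mosaic11p.bulk import LocusSpec


@pytest.fixture
def cnloh_locus():
    return LocusSpec("chr11", 1, 2_800_000, "cn_LOH")


@pytest.fixture
def dup_locus():
    return LocusSpec("chr11", 1, 2_800_000, "paternal_dup")


def make_sites(rows):
    """SNP table from (pos, ref_nt, alt_nt, ref_t, alt_t) tuples on chr11."""
    return pd.DataFrame(
        rows, columns=["pos", "ref_nt", "alt_nt", "ref_t", "alt_t"]
    ).assign(chrom="chr11")[["chrom", "pos", "ref_nt", "alt_nt", "ref_t", "alt_t"]]


@pytest.fixture
def balanced_sites():
    """Three germline-het sites: tumor alt-skewed, ref-skewed, and balanced."""
    return make_sites(
        [
            (100, 10, 10, 2, 18),   # tumor BAF 0.9 -> gained allele is alt
            (200, 10, 10, 18, 2),   # tumor BAF 0.1 -> gained allele is ref
            (300, 10, 10, 10, 10),  # tumor BAF exactly 0.5 -> dropped
        ]
    )


@pytest.fixture
def mlpa_probes():
    """One-sample probe profile builder."""

    def build(ic1_values, ic2_values, sample_id="S000", excluded_value=None):
        rows = []
        for i, v in enumerate(ic1_values):
            rows.append((sample_id, f"IC1_{chr(65 + i)}", "IC1", v))
        if excluded_value is not None:
            rows.append((sample_id, "H19.11.001.976583", "IC1", excluded_value))
        for i, v in enumerate(ic2_values):
            rows.append((sample_id, f"IC2_{chr(65 + i)}", "IC2", v))
        return pd.DataFrame(rows, columns=["sample_id", "probe_id", "target", "value"])

    return build


def exhaustive_kmeans_split(values):
    """Optimal 2-partition of 1-D data by brute force over all subsets.

    Enumerates every 2-subset partition (feasible for n <= ~14), returning
    the threshold (midpoint of the two cluster means) of the partition
    minimizing the total within-cluster sum of squares, or None when
    degenerate.  Independent oracle for the k-means implementation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return None
    best = (np.inf, None)
    for mask in range(1, 2**n - 1):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        left, right = x[sel], x[~sel]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best[0]:
            best = (ss, (left.mean() + right.mean()) / 2.0)
    return best[1]
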