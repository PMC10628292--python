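"""Imprinting-center methylation: means, ratio, epimutation calls, RRBS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaic11p.methylation import (
    DEFAULT_IC_REGIONS,
    MethylationModel,
    PromoterRegion,
    classify_epimutation,
    classify_mosaic_by_ratio,
    ic_means,
    ic_ratio,
    kmeans_threshold,
    mosaic_fraction_methylation,
    rrbs_region_methylation,
)
from conftest import exhaustive_kmeans_split


def test_ic_means_basic(mlpa_probes):
    probes = mlpa_probes([0.6, 0.6, 0.6], [0.4, 0.5, 0.5, 0.6])
    assert ic_means(probes) == pytest.approx((0.6, 0.5))


def test_ic_means_applies_default_exclusion(mlpa_probes):
    # the non-discriminating IC1 probe is dropped even without an excluded flag
    probes = mlpa_probes([0.5, 0.7, 0.9], [0.5] * 4, excluded_value=0.1)
    ic1, _ = ic_means(probes)
    assert ic1 == pytest.approx(0.7)


def test_ic_means_errors_when_target_fully_excluded(mlpa_probes):
    probes = mlpa_probes([], [0.5] * 4, excluded_value=0.1)
    with pytest.raises(ValueError, match="IC1"):
        ic_means(probes)


@pytest.mark.parametrize(
    "ic1,ic2,expected", [(0.6, 0.6, 1.0), (0.75, 0.5, 1.5), (0.5, 1.0, 0.5)]
)
def test_ic_ratio(ic1, ic2, expected):
    assert ic_ratio(ic1, ic2) == pytest.approx(expected)


def test_ic_ratio_requires_positive_ic2():
    with pytest.raises(ValueError):
        ic_ratio(0.5, 0.0)


@pytest.mark.parametrize(
    "ic1,ic2,expected", [(0.6, 0.6, 0.0), (0.625, 0.375, 25.0), (1.0, 0.0, 100.0)]
)
def test_mosaic_fraction_methylation(ic1, ic2, expected):
    assert mosaic_fraction_methylation(ic1, ic2) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(rho=st.floats(min_value=0.0, max_value=1.0))
def test_symmetric_mixture_recovers_rho_exactly(rho):
    ic1, ic2 = 0.5 * (1 + rho), 0.5 * (1 - rho)
    assert mosaic_fraction_methylation(ic1, ic2) == pytest.approx(100 * rho, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(
    ic1=st.floats(min_value=0.05, max_value=1.0),
    ic2=st.floats(min_value=0.05, max_value=1.0),
)
def test_unit_ratio_iff_zero_fraction(ic1, ic2):
    hi, lo = max(ic1, ic2), min(ic1, ic2)  # keep the fraction on the unclamped side
    ratio_is_one = ic_ratio(hi, lo) == pytest.approx(1.0, abs=1e-12)
    fraction_zero = mosaic_fraction_methylation(hi, lo) == pytest.approx(0.0, abs=1e-9)
    assert ratio_is_one == fraction_zero


def test_kmeans_threshold_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(4, 13))
        n_hi = int(rng.integers(1, n))
        values = np.concatenate(
            [rng.normal(0.5, 0.05, n - n_hi), rng.normal(0.85, 0.05, n_hi)]
        ).clip(0, 1)
        assert kmeans_threshold(values) == pytest.approx(
            exhaustive_kmeans_split(values), abs=1e-9
        )


def test_kmeans_threshold_cross_checked_against_sklearn():
    """On well-separated cohorts the exact split equals sklearn's Lloyd."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(8)
    for _ in range(10):
        values = np.concatenate(
            [rng.normal(0.5, 0.03, 20), rng.normal(0.9, 0.03, 8)]
        ).clip(0, 1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(values.reshape(-1, 1))
        centers = np.sort(km.cluster_centers_.ravel())
        assert kmeans_threshold(values) == pytest.approx(centers.mean(), abs=1e-9)


def test_kmeans_threshold_degenerate_returns_none():
    assert kmeans_threshold([0.5, 0.5, 0.5]) is None
    assert kmeans_threshold([0.5]) is None


def _cohort(ic1_by_sample, ic2_by_sample):
    rows = []
    for sid, vals in ic1_by_sample.items():
        for i, v in enumerate(vals):
            rows.append((sid, f"IC1_{i}", "IC1", v))
    for sid, vals in ic2_by_sample.items():
        for i, v in enumerate(vals):
            rows.append((sid, f"IC2_{i}", "IC2", v))
    return pd.DataFrame(rows, columns=["sample_id", "probe_id", "target", "value"])


def test_classify_epimutation_gom_and_rules():
    rng = np.random.default_rng(0)
    ic1 = {f"N{i}": rng.normal(0.5, 0.02, 3) for i in range(10)}
    ic2 = {f"N{i}": rng.normal(0.5, 0.02, 4) for i in range(10)}
    # full GOM-IC1 sample; another with a single elevated probe (below the 2/3 rule)
    ic1["GOM"] = np.array([0.9, 0.9, 0.9]); ic2["GOM"] = rng.normal(0.5, 0.02, 4)
    ic1["ONE"] = np.array([0.9, 0.5, 0.5]); ic2["ONE"] = rng.normal(0.5, 0.02, 4)
    # LOM-IC2 with exactly 2 of 4 probes in the loss direction
    ic1["LOM2"] = rng.normal(0.5, 0.02, 3); ic2["LOM2"] = np.array([0.1, 0.1, 0.5, 0.5])
    calls = classify_epimutation(_cohort(ic1, ic2))
    assert calls.loc["GOM", "gom_ic1"] and not calls.loc["GOM", "lom_ic2"]
    assert not calls.loc["ONE", "gom_ic1"]
    assert calls.loc["LOM2", "lom_ic2"] and not calls.loc["LOM2", "gom_ic1"]
    assert not calls.loc["N0", ["gom_ic1", "lom_ic2"]].any()


def test_classify_epimutation_degenerate_cohort_all_negative():
    ic1 = {f"S{i}": [0.5, 0.5, 0.5] for i in range(4)}
    ic2 = {f"S{i}": [0.5, 0.5, 0.5, 0.5] for i in range(4)}
    with pytest.warns(UserWarning, match="degenerate"):
        calls = classify_epimutation(_cohort(ic1, ic2))
    assert not calls.to_numpy().any()


def test_rrbs_region_methylation_pooled_counts():
    region = PromoterRegion("IC1", "chr11", 100, 200)
    cpgs = pd.DataFrame(
        {
            "chrom": ["chr11"] * 3,
            "pos": [100, 150, 500],
            "meth_count": [3, 1, 50],
            "unmeth_count": [1, 3, 0],
        }
    )
    # pooled-count ratio (4/8), not the mean of per-CpG ratios; pos 500 excluded
    assert rrbs_region_methylation(cpgs, region) == pytest.approx(0.5)
    assert rrbs_region_methylation(
        cpgs.assign(unmeth_count=0), region
    ) == pytest.approx(1.0)


def test_rrbs_no_covered_cpg_is_absent():
    region = DEFAULT_IC_REGIONS["IC1"]
    cpgs = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [2_000_000], "meth_count": [5], "unmeth_count": [5]}
    )
    assert rrbs_region_methylation(cpgs, region) is None


@settings(derandomize=True, max_examples=50)
@given(perm_seed=st.integers(min_value=0, max_value=10_000))
def test_rrbs_invariant_to_order_and_record_splitting(perm_seed):
    region = PromoterRegion("IC1", "chr11", 1, 1000)
    rng = np.random.default_rng(7)
    cpgs = pd.DataFrame(
        {
            "chrom": "chr11",
            "pos": np.arange(10, 110, 10),
            "meth_count": rng.integers(0, 20, 10),
            "unmeth_count": rng.integers(1, 20, 10),
        }
    )
    base = rrbs_region_methylation(cpgs, region)
    perm = cpgs.sample(frac=1, random_state=perm_seed).reset_index(drop=True)
    assert rrbs_region_methylation(perm, region) == pytest.approx(base)
    # split each CpG's counts across duplicate records
    half = cpgs.copy()
    half["meth_count"] //= 2
    half["unmeth_count"] //= 2
    rest = cpgs.copy()
    rest["meth_count"] -= half["meth_count"]
    rest["unmeth_count"] -= half["unmeth_count"]
    split = pd.concat([half, rest], ignore_index=True)
    assert rrbs_region_methylation(split, region) == pytest.approx(base)


def test_classify_mosaic_by_ratio_rules():
    rng = np.random.default_rng(3)
    normals = rng.normal(1.0, 0.02, 50)
    assert not classify_mosaic_by_ratio(1.0, normals)
    assert classify_mosaic_by_ratio(1.5, normals)
    # exactly at mean + 3 SD: strict inequality, not flagged
    # (cohort chosen so mean=1.5 and SD=1.0 are exact in floating point)
    exact = [1.0, 1.0, 1.0, 3.0]
    assert not classify_mosaic_by_ratio(1.5 + 3.0, exact)
    assert classify_mosaic_by_ratio(1.5 + 3.0 + 1e-9, exact)
    with pytest.raises(ValueError):
        classify_mosaic_by_ratio(1.0, np.ones(10))


def test_methylation_model_fit(mlpa_probes):
    cohort = pd.concat(
        [
            mlpa_probes([0.5, 0.5, 0.5], [0.5] * 4, sample_id=f"N{i}")
            for i in range(6)
        ]
        + [mlpa_probes([0.62, 0.63, 0.62], [0.37, 0.38, 0.38, 0.37], sample_id="MOS")],
        ignore_index=True,
    )
    # tiny jitter so per-probe clustering is not degenerate
    rng = np.random.default_rng(11)
    cohort["value"] = (cohort["value"] + rng.normal(0, 0.01, len(cohort))).clip(0, 1)
    res = MethylationModel(cohort, normal_ratios=rng.normal(1.0, 0.02, 30)).fit()
    mos = res.samples.loc["MOS"]
    assert mos["fraction_pct"] == pytest.approx(25.0, abs=5.0)
    assert bool(mos["mosaic_flag"])
    assert "Imprinting-center" in res.summary()
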