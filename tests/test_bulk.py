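"""Bulk BAF mosaicism estimator: filters, formulas, binomial detection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaic11p.bulk import (
    BulkMosaicModel,
    LocusSpec,
    NoInformativeSnpsError,
    area_fraction,
    compute_baf,
    detect_mosaicism,
    estimate_gaf,
    mosaic_fraction_cnloh,
    mosaic_fraction_general,
    orient_gained_alleles,
)
from conftest import make_sites


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(10, 10, 0.5), (0, 7, 1.0), (67, 133, 0.665), (5, 0, 0.0)],
)
def test_compute_baf_values(ref, alt, expected):
    assert compute_baf(ref, alt) == pytest.approx(expected)


def test_compute_baf_zero_depth_is_undefined_and_negative_rejected():
    assert math.isnan(compute_baf(0, 0))
    with pytest.raises(ValueError):
        compute_baf(-1, 5)


def test_orientation_filters_and_flags(balanced_sites, cnloh_locus):
    oriented = orient_gained_alleles(balanced_sites, cnloh_locus)
    # tumor BAF exactly 0.5 dropped; 2 of 3 sites retained
    assert len(oriented) == 2
    flags = dict(zip(oriented["pos"], oriented["gained_is_alt"]))
    assert bool(flags[100]) and not bool(flags[200])


def test_orientation_drops_homozygous_and_low_depth(cnloh_locus):
    sites = make_sites(
        [
            (100, 20, 0, 2, 18),  # germline homozygous ref (BAF 0)
            (200, 3, 3, 2, 18),   # depth 6 < 8
            (300, 10, 10, 2, 18),
        ]
    )
    oriented = orient_gained_alleles(sites, cnloh_locus)
    assert list(oriented["pos"]) == [300]


def test_orientation_on_germline_reference(cnloh_locus):
    # non-tumor shifted beyond the het window by high mosaicism, blood balanced
    sites = make_sites([(100, 3, 27, 0, 30)]).assign(ref_gl=15, alt_gl=15)
    assert orient_gained_alleles(sites, cnloh_locus, reference="nt").empty
    oriented = orient_gained_alleles(sites, cnloh_locus, reference="germline")
    assert len(oriented) == 1


@pytest.mark.parametrize(
    "bafs,flags,expected",
    [
        ([0.6, 0.7, 0.8], [True] * 3, 0.7),
        ([0.5, 0.5], [True, True], 0.5),
        ([0.66, 0.67, 0.68, 0.64], [True] * 4, 0.665),
        # gained allele on the reference side uses 1 - baf_nt
        ([0.3, 0.35, 0.25], [False] * 3, 0.7),
    ],
)
def test_estimate_gaf_median(bafs, flags, expected):
    depth = 1000
    oriented = pd.DataFrame(
        {
            "ref_nt": [round(depth * (1 - b)) for b in bafs],
            "alt_nt": [round(depth * b) for b in bafs],
            "baf_nt": bafs,
            "gained_is_alt": flags,
        }
    )
    assert estimate_gaf(oriented) == pytest.approx(expected)


def test_estimate_gaf_empty_errors():
    with pytest.raises(NoInformativeSnpsError):
        estimate_gaf(pd.DataFrame(columns=["baf_nt", "gained_is_alt"]))


@pytest.mark.parametrize(
    "gaf,alteration,expected",
    [
        (0.5, "cn_LOH", 0.0),
        (0.665, "cn_LOH", 33.0),
        (12 / 22, "paternal_dup", 20.0),
        (1.0, "cn_LOH", 100.0),
    ],
)
def test_mosaic_fraction_general(gaf, alteration, expected, cnloh_locus, dup_locus):
    locus = cnloh_locus if alteration == "cn_LOH" else dup_locus
    assert mosaic_fraction_general(gaf, locus) == pytest.approx(expected)


@pytest.mark.parametrize("gaf,expected", [(0.5, 0.0), (1.0, 100.0), (0.79, 58.0)])
def test_mosaic_fraction_cnloh(gaf, expected):
    assert mosaic_fraction_cnloh(gaf) == pytest.approx(expected)


def test_fraction_clamped_below_zero_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        assert mosaic_fraction_cnloh(0.45) == 0.0


def test_general_formula_matches_cnloh_special_case_on_grid(cnloh_locus):
    for gaf in np.arange(0.0, 1.0001, 0.01):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mosaic_fraction_general(float(gaf), cnloh_locus) == pytest.approx(
                mosaic_fraction_cnloh(float(gaf)), abs=1e-12
            )


@settings(derandomize=True, max_examples=200)
@given(rho=st.floats(min_value=0.0, max_value=1.0))
def test_mixture_inversion_identities(rho):
    """Plugging the mixture dosage into the estimator returns rho exactly."""
    cnloh = LocusSpec("chr11", 1, 10, "cn_LOH")
    dup = LocusSpec("chr11", 1, 10, "paternal_dup")
    assert mosaic_fraction_general((1 + rho) / 2, cnloh) == pytest.approx(100 * rho, abs=1e-9)
    assert mosaic_fraction_general((1 + rho) / (2 + rho), dup) == pytest.approx(
        100 * rho, abs=1e-9
    )


@settings(derandomize=True, max_examples=100)
@given(
    g1=st.floats(min_value=0.5, max_value=1.0),
    g2=st.floats(min_value=0.5, max_value=1.0),
)
def test_fraction_monotone_in_gaf(g1, g2):
    locus = LocusSpec("chr11", 1, 10, "cn_LOH")
    lo, hi = sorted((g1, g2))
    assert mosaic_fraction_general(lo, locus) <= mosaic_fraction_general(hi, locus)


def _oriented_from_counts(gained, total):
    """Single-site oriented frame with the given gained/total read counts."""
    return pd.DataFrame(
        {
            "ref_nt": [total - gained],
            "alt_nt": [gained],
            "baf_nt": [gained / total],
            "gained_is_alt": [True],
        }
    )


def test_detection_pvalue_matches_exact_tail():
    """Aggregated p-value equals the exact binomial tail sum (small n)."""
    for gained, total in [(8, 10), (30, 50), (20, 40), (6, 6)]:
        est = detect_mosaicism(
            _oriented_from_counts(gained, total), LocusSpec("chr11", 1, 10)
        )
        tail = sum(
            math.comb(total, k) * 0.5**total for k in range(gained, total + 1)
        )
        assert est.p_value == pytest.approx(tail, rel=1e-12)


def test_detection_examples_balanced_vs_skewed(cnloh_locus):
    est_null = detect_mosaicism(_oriented_from_counts(600, 1200), cnloh_locus)
    assert est_null.p_value == pytest.approx(0.51, abs=0.01)
    assert not est_null.detected
    est_alt = detect_mosaicism(_oriented_from_counts(660, 1200), cnloh_locus)
    assert est_alt.p_value < 0.001 and est_alt.detected


def test_detection_saturated_signal(cnloh_locus):
    est = detect_mosaicism(_oriented_from_counts(20, 20), cnloh_locus)
    assert est.detected and est.fraction_pct == 100.0


@pytest.mark.parametrize(
    "mosaic,total,expected", [(0, 50, 0.0), (50, 50, 100.0), (14, 100, 14.0)]
)
def test_area_fraction(mosaic, total, expected):
    assert area_fraction(mosaic, total) == pytest.approx(expected)


def test_area_fraction_input_errors():
    with pytest.raises(ValueError):
        area_fraction(60, 50)
    with pytest.raises(ValueError):
        area_fraction(0, 0)


def test_model_fit_summary_roundtrip(cnloh_locus):
    rng = np.random.default_rng(0)
    n = 400
    alt_nt = rng.binomial(30, 0.65, n)
    alt_t = rng.binomial(90, 0.95, n)
    sites = pd.DataFrame(
        {
            "chrom": "chr11",
            "pos": np.arange(1, n + 1) * 100,
            "ref_nt": 30 - alt_nt,
            "alt_nt": alt_nt,
            "ref_t": 90 - alt_t,
            "alt_t": alt_t,
            "ref_gl": rng.binomial(30, 0.5, n),
        }
    )
    sites["alt_gl"] = 30 - sites["ref_gl"]
    res = BulkMosaicModel(sites, cnloh_locus).fit()
    assert res.detected
    assert res.fraction_pct == pytest.approx(30, abs=4)
    assert "fraction altered" in res.summary()
    assert {"gaf_nt", "fraction_pct", "p_value"}.issubset(res.to_frame().columns)
    assert (res.oriented_sites["p_snp"] <= 1).all()


def test_nt_reference_high_fraction_warns():
    rng = np.random.default_rng(1)
    n = 2000
    alt_nt = rng.binomial(60, 0.75, n)  # rho=0.5, deep enough to stay in window
    alt_t = rng.binomial(90, 1.0, n)
    sites = pd.DataFrame(
        {
            "chrom": "chr11",
            "pos": np.arange(1, n + 1),
            "ref_nt": 60 - alt_nt,
            "alt_nt": alt_nt,
            "ref_t": 90 - alt_t,
            "alt_t": alt_t,
        }
    )
    with pytest.warns(UserWarning, match="blood/germline"):
        res = BulkMosaicModel(sites, reference="nt").fit()
    assert res.fraction_pct > 40
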