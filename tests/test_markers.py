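"""ROC/AUC, Wilcoxon, delta intensity and the full screening chain."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from msimarkers import (
    ScreenParams,
    balanced_subsample,
    delta_intensity,
    discover_markers,
    roc_auc,
    wilcoxon_ranksum,
)
from msimarkers.errors import EmptyDataError, ParameterError
from msimarkers.markers import PRESETS
from msimarkers.peaks import FeatureMatrix


def brute_force_auc(a, b):
    """Exhaustive pairwise-count oracle: [#(x>y) + 0.5 #(x==y)] / (|a||b|)."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return wins / (len(a) * len(b))


def exact_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(a) + sorted(b)
    n1 = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    labels = list(range(len(pooled)))
    obs = sum(ranks[i] for i in range(n1))
    mean = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(labels, n1):
        stat = sum(ranks[i] for i in comb)
        total += 1
        if abs(stat - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([4, 5, 6], [1, 2, 3], 1.0),   # complete separation
        ([1, 2, 3], [1, 2, 3], 0.5),   # identical samples
        ([1, 2], [2, 3], 0.125),       # frozen from the brute-force oracle
    ],
)
def test_roc_auc_examples(a, b, expected):
    assert roc_auc(a, b) == pytest.approx(expected, abs=1e-12)
    assert roc_auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)


def test_roc_auc_empty_rejected():
    with pytest.raises(EmptyDataError):
        roc_auc([], [1.0])


@given(
    a=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=8),
    b=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=8),
)
def test_roc_auc_matches_oracle_and_complement(a, b):
    auc = roc_auc(a, b)
    assert auc == pytest.approx(brute_force_auc(a, b), abs=1e-12)
    assert auc + roc_auc(b, a) == pytest.approx(1.0, abs=1e-12)


def test_roc_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 5, 20)
    b = rng.uniform(1, 6, 25)
    before = roc_auc(a, b)
    assert roc_auc(np.exp(a), np.exp(b)) == pytest.approx(before, abs=1e-12)
    assert roc_auc(a**3, b**3) == pytest.approx(before, abs=1e-12)


# ---------------------------------------------------------------------------
# wilcoxon
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_small_samples_p_one():
    assert wilcoxon_ranksum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=0.05)


def test_wilcoxon_exact_small_sample():
    # 2 of the 20 equally likely rank assignments are as extreme
    assert wilcoxon_ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_asymptotic_close_to_exact_enumeration_n15():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(0.8, 1.0, 7)
    p_asym = wilcoxon_ranksum(a, b, method="asymptotic")
    p_exact = exact_ranksum_p(list(a), list(b))
    assert abs(p_asym - p_exact) < 0.01


# ---------------------------------------------------------------------------
# delta intensity
# ---------------------------------------------------------------------------

def test_delta_intensity_arithmetic():
    assert delta_intensity([3, 3], [1, 1]) == pytest.approx(0.75)
    assert delta_intensity([2, 4], [3, 3]) == pytest.approx(0.5)
    assert math.isnan(delta_intensity([0.0], [0.0]))


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------

def _fm_two_groups(n_pos, n_neg, n_bins=3, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 1, (n_pos + n_neg, n_bins))
    idx = pd.DataFrame(
        {
            "x": np.arange(n_pos + n_neg) + 1,
            "y": 1,
            "roi": "r",
            "patient": "P",
            "group": ["+RD"] * n_pos + ["-RD"] * n_neg,
        }
    )
    return FeatureMatrix(values, 800.0 + np.arange(n_bins), 0.156, idx)


def test_balanced_subsample_caps_both_groups():
    fm = _fm_two_groups(2000, 2000)
    sub = balanced_subsample(fm, 1500, seed=3)
    counts = sub.spot_index["group"].value_counts()
    assert counts["+RD"] == 1500 and counts["-RD"] == 1500


def test_balanced_subsample_keeps_smaller_group_whole():
    fm = _fm_two_groups(800, 2000)
    sub = balanced_subsample(fm, 1500, seed=3)
    counts = sub.spot_index["group"].value_counts()
    assert counts["+RD"] == 800 and counts["-RD"] == 1500


def test_balanced_subsample_reproducible():
    fm = _fm_two_groups(100, 100)
    s1 = balanced_subsample(fm, 50, seed=9)
    s2 = balanced_subsample(fm, 50, seed=9)
    np.testing.assert_array_equal(s1.values, s2.values)
    assert s1.spot_index.equals(s2.spot_index)


# ---------------------------------------------------------------------------
# discover_markers
# ---------------------------------------------------------------------------

def test_single_bin_complete_separation_passes():
    values = np.concatenate([np.full(30, 5.0), np.full(30, 1.0)])[:, None]
    idx = pd.DataFrame(
        {
            "x": np.arange(60) + 1,
            "y": 1,
            "roi": "r",
            "patient": "P",
            "group": ["+RD"] * 30 + ["-RD"] * 30,
        }
    )
    fm = FeatureMatrix(values, np.array([900.0]), 0.156, idx)
    res = discover_markers(fm, ScreenParams(subsample_n=30))
    assert len(res) == 1
    assert res[0].auc == 1.0
    assert res[0].passed
    assert res[0].direction == "up-in-+RD"


def test_discover_markers_invariant_to_row_order():
    # with subsample_n >= group sizes the screen is deterministic, so
    # shuffling the spectra must not change any per-bin statistic
    fm = _fm_two_groups(80, 80, n_bins=5, seed=4)
    fm.values[:80, 2] += 3.0  # make bin 2 discriminative
    res1 = discover_markers(fm, ScreenParams(subsample_n=100))
    rng = np.random.default_rng(0)
    perm = rng.permutation(fm.n_spots)
    fm2 = fm.subset_rows(perm)
    res2 = discover_markers(fm2, ScreenParams(subsample_n=100))
    assert [(r.bin_center, r.auc, r.passed) for r in res1] == [
        (r.bin_center, r.auc, r.passed) for r in res2
    ]
    np.testing.assert_allclose(
        [r.p_value for r in res1], [r.p_value for r in res2], equal_nan=True
    )


def test_results_sorted_by_discriminative_strength():
    fm = _fm_two_groups(60, 60, n_bins=4, seed=5)
    fm.values[:60, 1] += 2.0
    res = discover_markers(fm, ScreenParams(subsample_n=60))
    strengths = [abs(r.auc - 0.5) for r in res]
    assert strengths == sorted(strengths, reverse=True)
    assert len(res) == 4  # every bin reported


def test_screen_params_validation_and_presets():
    with pytest.raises(ParameterError):
        ScreenParams(auc_hi=0.4)
    with pytest.raises(ParameterError):
        ScreenParams(p_cut=0.0)
    assert PRESETS["results2020"].auc_hi == 0.6
    assert PRESETS["results2020"].delta_hi is None
    assert PRESETS["methods"].p_cut == 0.001
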