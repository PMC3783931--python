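"""Evaluation statistics against brute-force oracles and printed-count
worked examples."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from strokemismatch.evaluation import (
    ConfusionMatrix,
    build_confusion,
    classification_metrics,
    group_summary,
    mismatch_salvage,
    rank_sum_test,
    volumetric_agreement,
)
from strokemismatch.image_io import VolumeImage
from strokemismatch.lesion_segmentation import LesionMask


def _lesion(arr):
    template = VolumeImage(np.zeros(np.asarray(arr).shape), (10.0, 10.0, 10.0))
    return LesionMask.from_binary(np.asarray(arr, dtype=bool), template, "TTP")


class TestConfusion:
    def test_counts_from_flag_lists(self):
        predicted = [True] * 112 + [False] * 12 + [True] * 30 + [False] * 74
        actual = [True] * 112 + [False] * 12 + [False] * 30 + [True] * 74
        cm = build_confusion(predicted, actual)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (112, 12, 30, 74)
        assert cm.total == 228

    def test_all_agree_positive(self):
        cm = build_confusion([True] * 9, [True] * 9)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (9, 0, 0, 0)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([], [])

    def test_length_mismatch_and_unknowns_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([True], [True, False])
        with pytest.raises(ValueError):
            build_confusion([True, None], [True, False])

    def test_metrics_equal_direct_counting_on_random_cohorts(self):
        """classification_metrics(build_confusion(...)) == counting oracle."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            p = rng.random(n) > 0.5
            a = rng.random(n) > 0.5
            m = classification_metrics(build_confusion(list(p), list(a)))
            tp = int(np.sum(p & a))
            fn = int(np.sum(~p & a))
            tn = int(np.sum(~p & ~a))
            fp = int(np.sum(p & ~a))
            if tp + fn:
                assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
            else:
                assert m.sensitivity is None
            if tn + fp:
                assert m.specificity == pytest.approx(100 * tn / (tn + fp))
            else:
                assert m.specificity is None

    def test_degenerate_matrix_all_undefined(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)
        m = classification_metrics(ConfusionMatrix(0, 0, 0, 0))
        assert m.sensitivity is None and m.specificity is None
        assert m.ppv is None and m.npv is None

    def test_perfect_sensitivity_when_no_false_negatives(self):
        m = classification_metrics(ConfusionMatrix(tp=5, tn=2, fp=3, fn=0))
        assert m.sensitivity == pytest.approx(100.0)


def _brute_force_spearman(a, b):
    """Rank correlation from first principles: average ranks, Pearson on ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    ra, rb = ranks(list(a)), ranks(list(b))
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den


class TestVolumetricAgreement:
    def test_identical_vectors(self):
        s = volumetric_agreement([1, 5, 9, 13], [1, 5, 9, 13])
        assert s.spearman_rho == pytest.approx(1.0)
        assert s.mean_difference_mL == 0.0
        assert s.sd_difference_mL == 0.0

    def test_constant_shift(self):
        a = np.array([10.0, 20.0, 35.0, 50.0])
        s = volumetric_agreement(a, a + 8.0)
        assert s.mean_difference_mL == pytest.approx(-8.0)
        assert s.sd_difference_mL == pytest.approx(0.0)
        assert s.limits_of_agreement_mL[0] == pytest.approx(-8.0)

    def test_spearman_matches_brute_force_with_ties(self):
        a = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        b = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0]
        s = volumetric_agreement(a, b)
        assert s.spearman_rho == pytest.approx(_brute_force_spearman(a, b), abs=1e-12)

    def test_limits_are_mean_plus_minus_two_sd(self):
        rng = np.random.default_rng(11)
        a = rng.normal(50, 30, 40)
        b = a + rng.normal(8, 35, 40)
        s = volumetric_agreement(a, b)
        lo, hi = s.limits_of_agreement_mL
        assert lo == pytest.approx(s.mean_difference_mL - 2 * s.sd_difference_mL)
        assert hi == pytest.approx(s.mean_difference_mL + 2 * s.sd_difference_mL)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(1, 100, 25)
        b = rng.uniform(1, 100, 25)
        base = volumetric_agreement(a, b).spearman_rho
        assert volumetric_agreement(np.log(a), b).spearman_rho == pytest.approx(base)
        assert volumetric_agreement(a, b**3).spearman_rho == pytest.approx(base)

    def test_constant_vector_rho_undefined(self):
        s = volumetric_agreement([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert s.spearman_rho is None


class TestSalvage:
    def test_partial_overlap(self):
        mismatch = _lesion(np.arange(64).reshape(4, 4, 4) < 50)
        infarct = _lesion(np.arange(64).reshape(4, 4, 4) < 10)
        s = mismatch_salvage(mismatch, infarct)
        assert s.salvage_mL == pytest.approx(40.0)
        assert s.acute_mismatch_mL == pytest.approx(50.0)

    def test_infarct_covering_mismatch_gives_zero(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[0] = True
        s = mismatch_salvage(_lesion(arr), _lesion(np.ones((3, 3, 3), dtype=bool)))
        assert s.salvage_mL == 0.0

    def test_empty_infarct_preserves_mismatch(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[:2] = True
        s = mismatch_salvage(_lesion(arr), _lesion(np.zeros((3, 3, 3), dtype=bool)))
        assert s.salvage_mL == pytest.approx(s.acute_mismatch_mL)

    def test_conservation(self):
        rng = np.random.default_rng(13)
        mm = rng.random((5, 5, 4)) > 0.5
        inf = rng.random((5, 5, 4)) > 0.5
        s = mismatch_salvage(_lesion(mm), _lesion(inf))
        inter_mL = float(np.sum(mm & inf))  # 1 mL voxels
        assert s.salvage_mL + inter_mL == pytest.approx(s.acute_mismatch_mL)


def _enumerate_rank_sum_p(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled
    sample and counting U statistics at least as extreme."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(indices):
        xs = [pooled[i] for i in indices]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(indices)]
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    observed = u_of(tuple(range(n1)))
    mean_u = n1 * (len(pooled) - n1) / 2.0
    obs_dev = abs(observed - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_fully_separated_small_groups(self):
        """x below y entirely: U = 0 and exact two-sided p = 2/C(6,3) = 0.1."""
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        x = [12.1, 3.4, 7.7, 9.0, 1.2, 15.5, 6.1, 2.2]
        y = [8.8, 14.2, 16.9, 11.1, 13.0, 5.5, 18.8, 10.0]
        u, p = rank_sum_test(x, y)
        assert p == pytest.approx(_enumerate_rank_sum_p(x, y), abs=1e-9)

    def test_asymptotic_approximation_close_to_enumeration(self):
        # ties force the normal-approximation path; enumeration stays exact
        x = [1.0, 2.0, 2.0, 5.0, 7.0, 8.0, 9.0, 12.0]
        y = [2.0, 6.0, 10.0, 11.0, 13.0, 14.0, 15.0, 16.0]
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(_enumerate_rank_sum_p(x, y), abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestGroupSummary:
    def test_median_of_skewed_group(self):
        df = pd.DataFrame({"cell": ["tn"] * 3, "mismatch_mL": [0.0, 0.0, 22.0]})
        out = group_summary(df)
        assert out["tn"]["mismatch_mL"]["median"] == 0.0

    def test_single_element_group(self):
        df = pd.DataFrame({"cell": ["fp"], "mismatch_mL": [73.4]})
        out = group_summary(df)
        stats = out["fp"]["mismatch_mL"]
        assert stats["median"] == stats["q25"] == stats["q75"] == 73.4

    def test_empty_group_markers(self):
        df = pd.DataFrame({"cell": ["tp", "tp"], "mismatch_mL": [5.0, 7.0]})
        out = group_summary(df)
        assert out["tn"]["mismatch_mL"]["median"] is None
        assert out["tn"]["mismatch_mL"]["n"] == 0

    def test_percentiles_match_brute_force_linear_interpolation(self):
        values = [3.0, 8.0, 1.0, 9.0, 4.0, 6.0, 2.0]
        df = pd.DataFrame({"cell": ["tp"] * 7, "mismatch_mL": values})
        out = group_summary(df)["tp"]["mismatch_mL"]
        # brute force: sort, position p*(n-1), linear interpolation
        v = sorted(values)

        def brute(p):
            pos = p * (len(v) - 1)
            lo = int(math.floor(pos))
            hi = int(math.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        assert out["q25"] == pytest.approx(brute(0.25))
        assert out["median"] == pytest.approx(brute(0.5))
        assert out["q75"] == pytest.approx(brute(0.75))

    def test_delta_nihss_sign_convention(self):
        # improvement (acute 11 -> 4 at 24 h) is positive
        df = pd.DataFrame(
            {"cell": ["tp"], "nihss_acute": [11], "nihss_24h": [4]}
        )
        out = group_summary(df)
        assert out["tp"]["delta_nihss"]["median"] == 7.0
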