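"""Questionnaire scoring, normative thresholds and exposure labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stresscost as sc
from stresscost.msit_exposure import (
    DIMENSIONS,
    N_ITEMS,
    MsitValidationError,
    reverse_code,
    risk_band,
    score_questionnaire_frame,
)


def brute_force_dimension_means(items, item_map):
    """Independent oracle: loop-and-average per dimension, reverse-coding by hand."""
    means = {}
    for dim in DIMENSIONS:
        vals = []
        for idx in item_map.items_of(dim):
            v = items[idx - 1]
            if v is not None:
                vals.append(6 - v if item_map.reverse[idx - 1] else v)
        means[dim] = sum(vals) / len(vals) if vals else None
    return means


def brute_force_percentile(sample, q):
    """Linear interpolation between order statistics, written from scratch."""
    xs = sorted(sample)
    h = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestItemMap:
    def test_default_layout_covers_all_items(self, item_map):
        counts = {d: len(item_map.items_of(d)) for d in DIMENSIONS}
        assert sum(counts.values()) == N_ITEMS
        assert all(c >= 1 for c in counts.values())
        # the standard layout: 8 demands and 4 relationships items reverse-coded
        assert sum(item_map.reverse) == 12

    def test_bad_maps_rejected(self):
        with pytest.raises(MsitValidationError):
            sc.ItemMap(dimensions=("demands",) * N_ITEMS, reverse=(False,) * N_ITEMS)
        with pytest.raises(MsitValidationError):
            sc.ItemMap(dimensions=("demands",) * 10, reverse=(False,) * 10)


class TestScoring:
    def test_constant_fives_score_five_without_reversal(self, item_map):
        # polarity flags off: all answers 5 -> every dimension mean is 5
        flat = sc.ItemMap(dimensions=item_map.dimensions, reverse=(False,) * N_ITEMS)
        resp = sc.MsitResponse("w1", (5,) * N_ITEMS)
        scores = sc.score_dimensions(resp, flat)
        assert scores.valid
        assert all(scores.scores[d] == 5.0 for d in DIMENSIONS)

    def test_all_threes_are_a_fixed_point_of_reverse_coding(self, item_map):
        resp = sc.MsitResponse("w1", (3,) * N_ITEMS)
        scores = sc.score_dimensions(resp, item_map)
        assert all(scores.scores[d] == 3.0 for d in DIMENSIONS)

    def test_dimension_means_match_brute_force_oracle(self, item_map):
        rng = np.random.default_rng(5)
        for _ in range(20):
            items = tuple(
                None if rng.random() < 0.1 else int(rng.integers(1, 6))
                for _ in range(N_ITEMS)
            )
            got = sc.score_dimensions(sc.MsitResponse("w", items), item_map)
            want = brute_force_dimension_means(items, item_map)
            for dim in DIMENSIONS:
                if want[dim] is None or got.scores[dim] is None:
                    # completion rule may drop a sparsely answered dimension
                    continue
                assert got.scores[dim] == pytest.approx(want[dim])

    def test_out_of_range_item_names_worker_and_index(self):
        with pytest.raises(MsitValidationError, match=r"worker w9.*item 3"):
            sc.MsitResponse("w9", (1, 2, 7) + (3,) * 32)

    def test_completion_rule_drops_sparse_dimension(self, item_map):
        # blank out every demands item (8 of them) -> demands missing, invalid
        items = [3] * N_ITEMS
        for idx in item_map.items_of("demands"):
            items[idx - 1] = None
        scores = sc.score_dimensions(sc.MsitResponse("w", tuple(items)), item_map)
        assert scores.scores["demands"] is None
        assert not scores.valid
        assert sc.overall_score(scores) is None

    @given(st.integers(min_value=1, max_value=5))
    def test_reverse_coding_is_an_involution(self, v):
        assert reverse_code(reverse_code(v)) == v
        assert 1 <= reverse_code(v) <= 5


class TestOverallScore:
    def _valid_scores(self, values):
        return sc.DimensionScores("w", dict(zip(DIMENSIONS, values)), valid=True)

    def test_constant_dimensions(self):
        assert sc.overall_score(self._valid_scores([4.2] * 7)) == pytest.approx(4.2)

    def test_arithmetic_mean(self):
        assert sc.overall_score(self._valid_scores([1, 2, 3, 4, 5, 1, 5])) == pytest.approx(3.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.permutations([1.0, 2.0, 2.5, 3.5, 4.0, 4.5, 5.0]))
    def test_permutation_invariance(self, perm):
        base = sc.overall_score(self._valid_scores([1.0, 2.0, 2.5, 3.5, 4.0, 4.5, 5.0]))
        assert sc.overall_score(self._valid_scores(perm)) == pytest.approx(base)

    def test_item_mean_weights_dimensions_by_item_count(self, item_map):
        # demands (8 items, reverse-coded) at raw 1 -> coded 5; rest at 3
        items = [3] * N_ITEMS
        for idx in item_map.items_of("demands"):
            items[idx - 1] = 1
        resp = sc.MsitResponse("w", tuple(items))
        scores = sc.score_dimensions(resp, item_map)
        dim_mean = sc.overall_score(scores)
        item_mean = sc.overall_score(scores, method="item_mean", response=resp, item_map=item_map)
        # 8/35 items at 5, 27/35 at 3 vs 1/7 dimensions at 5, 6/7 at 3
        assert item_mean == pytest.approx((8 * 5 + 27 * 3) / 35)
        assert dim_mean == pytest.approx((5 + 6 * 3) / 7)


class TestThresholds:
    def test_band_cutoffs_match_brute_force_percentiles(self):
        sample = np.arange(1, 101, dtype=float)
        thr = sc.derive_thresholds(sample)
        for got, q in zip(thr.band_cutoffs, (20, 50, 80)):
            assert got == pytest.approx(brute_force_percentile(sample, q))
        assert thr.band_cutoffs == pytest.approx((20.8, 50.5, 80.2))
        assert thr.binary_cutoff == pytest.approx(brute_force_percentile(sample, 25))

    def test_degenerate_constant_sample(self):
        thr = sc.derive_thresholds([4.0] * 25)
        assert thr.binary_cutoff == 4.0
        assert thr.band_cutoffs == (4.0, 4.0, 4.0)

    def test_small_or_nonfinite_samples_rejected(self):
        with pytest.raises(MsitValidationError):
            sc.derive_thresholds([3.0] * 19)
        with pytest.raises(MsitValidationError):
            sc.derive_thresholds([np.nan] + [3.0] * 24)

    def test_cutoff_splits_sample_near_the_nominal_fraction(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(3.0, 0.5, size=1000)
        thr = sc.derive_thresholds(sample, binary_percentile=25)
        below = np.mean(sample < thr.binary_cutoff)
        at_or_below = np.mean(sample <= thr.binary_cutoff)
        assert below <= 0.25 + 1 / len(sample)
        assert at_or_below >= 0.25 - 1 / len(sample)


class TestClassification:
    def test_tie_is_exposed_and_epsilon_above_is_unexposed(self, uniform_thresholds):
        cut = uniform_thresholds.binary_cutoff
        assert sc.classify_exposure(cut, uniform_thresholds).status == "exposed"
        assert sc.classify_exposure(cut + 1e-9, uniform_thresholds).status == "unexposed"

    def test_missing_score_is_unknown(self, uniform_thresholds):
        lab = sc.classify_exposure(None, uniform_thresholds, worker_id="w")
        assert lab.status == "unknown"
        assert lab.risk_band == "unknown"
        assert sc.classify_exposure(float("nan"), uniform_thresholds).status == "unknown"

    @pytest.mark.parametrize(
        "score,band",
        [(10, "high"), (30, "medium-high"), (60, "medium-low"), (95, "low")],
    )
    def test_risk_bands_from_uniform_normative(self, uniform_thresholds, score, band):
        assert sc.classify_exposure(score, uniform_thresholds).risk_band == band

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1.0, max_value=5.0, allow_nan=False),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_classification_monotone_in_score(self, score, bump):
        thr = sc.ExposureThresholds(
            binary_cutoff=2.6, band_cutoffs=(2.4, 3.1, 3.9), normative_n=100
        )
        lo = sc.classify_exposure(score, thr).status
        hi = sc.classify_exposure(min(score + bump, 5.0), thr).status
        assert not (lo == "unexposed" and hi == "exposed")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_every_finite_score_gets_exactly_one_band(self, score):
        thr = sc.ExposureThresholds(
            binary_cutoff=2.6, band_cutoffs=(2.4, 3.1, 3.9), normative_n=100
        )
        assert risk_band(score, thr) in ("high", "medium-high", "medium-low", "low")


class TestFrameScoring:
    def test_questionnaire_frame_scores_and_flags_incomplete(self, item_map):
        import pandas as pd

        cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
        full = dict(zip(cols, [3] * N_ITEMS))
        sparse = dict(full)
        for idx in item_map.items_of("change"):
            sparse[f"item_{idx:02d}"] = None
        frame = pd.DataFrame(
            [{"worker_id": "a", **full}, {"worker_id": "b", **sparse}]
        )
        scores = score_questionnaire_frame(frame, item_map)
        assert scores["a"] == pytest.approx(3.0)
        assert scores["b"] is None  # all 3 change items blank -> invalid
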