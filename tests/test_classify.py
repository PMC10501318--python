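"""Responder calling, exclusion rules, category assignment, group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from drgcal import (
    Category,
    ExclusionFlag,
    ProportionSummary,
    RoiSet,
    TraceMatrix,
    TraceStage,
    blinded_proportions,
    call_responders,
    classify_cells,
    compare_groups,
    flag_exclusions,
    responder_proportions,
)
from drgcal.classify import RESPONDER_CATEGORIES
from drgcal.synthetic import CellClass, cell_traces, generate_cells

from .conftest import brute_force_chi2


def _dff(values, schedule):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return TraceMatrix(
        values=values,
        cell_ids=tuple(range(1, values.shape[0] + 1)),
        frame_rate_hz=schedule.frame_rate_hz,
        episode_boundaries=schedule.episode_starts,
        stage=TraceStage.DFF,
    )


def _dff_with_peaks(peaks_by_episode, schedule):
    """Build a dF/F matrix whose per-episode response-window peaks are given;
    rows are cells, columns are episodes."""
    peaks = np.atleast_2d(np.asarray(peaks_by_episode, dtype=float))
    vals = np.zeros((peaks.shape[0], schedule.total_frames))
    for i, ep in enumerate(schedule.episodes):
        onset = schedule.episode_starts[i] + ep.onset_frame
        vals[:, onset + 2] = peaks[:, i]
    return _dff(vals, schedule)


class TestCallResponders:
    @pytest.mark.parametrize(
        "peak,expected",
        [(20.0, True), (4.9, False), (5.0, False), (5.0001, True), (-3.0, False)],
    )
    def test_strict_threshold(self, short_schedule, peak, expected):
        """The activation threshold is dF/F > 5%, strictly."""
        dff = _dff_with_peaks([[peak, 0.0, 0.0]], short_schedule)
        table = call_responders(dff, short_schedule, threshold_pct=5.0)
        assert bool(table.is_responder[0, 0]) is expected

    def test_peak_measured_after_onset_only(self, short_schedule):
        """Supra-threshold activity before the stimulus onset is not a
        response to that episode."""
        vals = np.zeros((1, short_schedule.total_frames))
        vals[0, short_schedule.episode_starts[1] + 1] = 50.0  # inside baseline
        table = call_responders(_dff(vals, short_schedule), short_schedule)
        assert not table.is_responder[0, 1]

    def test_frame_mismatch_rejected(self, short_schedule, default_schedule):
        dff = _dff(np.zeros((1, short_schedule.total_frames)), short_schedule)
        with pytest.raises(ValueError, match="frames"):
            call_responders(dff, default_schedule)

    def test_monotone_in_threshold(self, short_schedule):
        """Raising the threshold never increases any responder count."""
        rng = np.random.default_rng(0)
        dff = _dff_with_peaks(rng.uniform(0, 25, size=(30, 3)), short_schedule)
        prev = None
        for thr in range(1, 21):
            n = call_responders(dff, short_schedule, float(thr)).is_responder.sum()
            if prev is not None:
                assert n <= prev
            prev = n


class TestFlagExclusions:
    def test_spontaneous_baseline_activity_flagged(self, short_schedule):
        vals = np.zeros((1, short_schedule.total_frames))
        vals[0, 0:10] = 30.0  # whole baseline of episode 0 above threshold
        dff = _dff(vals, short_schedule)
        table = call_responders(dff, short_schedule)
        flags = flag_exclusions(dff, table, None, short_schedule)
        assert flags[1] is ExclusionFlag.SPONTANEOUS

    def test_brief_baseline_blip_not_flagged(self, short_schedule):
        vals = np.zeros((1, short_schedule.total_frames))
        vals[0, 3:5] = 30.0  # 2 consecutive frames < default run of 3
        dff = _dff(vals, short_schedule)
        flags = flag_exclusions(
            dff, call_responders(dff, short_schedule), None, short_schedule
        )
        assert 1 not in flags

    def test_persistent_after_response_flagged(self, short_schedule):
        vals = np.zeros((1, short_schedule.total_frames))
        onset = short_schedule.episode_starts[1] + short_schedule.episodes[1].onset_frame
        vals[0, onset:] = 30.0  # responds at episode 1 and never comes down
        # keep later baselines clean so only persistence applies
        for i in (2,):
            sl = short_schedule.episode_slice(i)
            vals[0, sl.start : sl.start + short_schedule.episodes[i].baseline_frames] = 0.0
        dff = _dff(vals, short_schedule)
        flags = flag_exclusions(
            dff, call_responders(dff, short_schedule), None, short_schedule
        )
        assert flags[1] is ExclusionFlag.PERSISTENT

    def test_transient_responder_not_persistent(self, short_schedule):
        dff = _dff_with_peaks([[20.0, 20.0, 20.0]], short_schedule)
        flags = flag_exclusions(
            dff, call_responders(dff, short_schedule), None, short_schedule
        )
        assert 1 not in flags

    def test_overlapping_pair_both_flagged(self, short_schedule):
        cells = generate_cells(
            {CellClass.SILENT: 1}, image_shape=(64, 64), seed=1,
            plant_overlap_pair=True,
        )
        rois = RoiSet.from_cells(cells, (64, 64))
        dff = _dff(np.zeros((3, short_schedule.total_frames)), short_schedule)
        flags = flag_exclusions(
            dff, call_responders(dff, short_schedule), rois, short_schedule
        )
        pair_ids = [c.cell_id for c in cells if c.planted_overlap]
        assert all(flags.get(i) is ExclusionFlag.OVERLAP for i in pair_ids)


class TestClassifyCells:
    def _classify(self, peaks, schedule, flags=None):
        dff = _dff_with_peaks(peaks, schedule)
        table = call_responders(dff, schedule)
        return classify_cells(table, flags or {}, schedule)

    @pytest.mark.parametrize(
        "peaks,expected",
        [
            # default 7-episode order: puff, skin brush, pinch, colon-brush
            # insert/extract, balloon insert, balloon inflate
            ([0, 0, 0, 0, 0, 0, 20], Category.INTERNAL),  # balloon inflate only
            ([20, 0, 20, 0, 0, 0, 0], Category.EXTERNAL_GENTLE),  # puff + pinch
            ([0, 0, 20, 0, 0, 0, 0], Category.EXTERNAL_NOXIOUS),  # pinch only
            ([20, 0, 0, 20, 0, 0, 0], Category.EXCLUDED_BOTH),  # puff + colon brush
            ([0, 15, 0, 0, 0, 0, 0], Category.EXTERNAL_GENTLE),  # skin brush only
            ([0, 0, 0, 20, 20, 20, 20], Category.INTERNAL),
            ([0, 0, 0, 0, 0, 0, 0], Category.NONRESPONDER),
        ],
    )
    def test_category_assignment(self, default_schedule, peaks, expected):
        (cls,) = self._classify([peaks], default_schedule)
        assert cls.category is expected

    def test_exclusion_flags_take_precedence(self, default_schedule):
        cls = self._classify(
            [[20, 0, 0, 20, 0, 0, 0]],
            default_schedule,
            flags={1: ExclusionFlag.SPONTANEOUS},
        )
        assert cls[0].category is Category.EXCLUDED_SPONTANEOUS

    def test_partition_covers_all_cells(self, default_schedule):
        """Every ROI lands in exactly one category; counts sum to the total."""
        rng = np.random.default_rng(3)
        peaks = rng.uniform(0, 30, size=(40, 7))
        classifications = self._classify(peaks, default_schedule)
        assert len(classifications) == 40
        from collections import Counter

        counts = Counter(c.category for c in classifications)
        assert sum(counts.values()) == 40


class TestProportions:
    def _summary(self, internal, noxious, gentle, extra=()):
        cats = (
            [Category.INTERNAL] * internal
            + [Category.EXTERNAL_NOXIOUS] * noxious
            + [Category.EXTERNAL_GENTLE] * gentle
            + list(extra)
        )
        from drgcal.classify import CellClassification

        cls = [
            CellClassification(cell_id=i + 1, category=c,
                               per_episode_responder=(), peak_dff=10.0)
            for i, c in enumerate(cats)
        ]
        return responder_proportions(cls)

    def test_pooled_percentages(self):
        s = self._summary(10, 5, 5)
        assert s.percentages[Category.INTERNAL] == pytest.approx(50.0)
        assert s.percentages[Category.EXTERNAL_NOXIOUS] == pytest.approx(25.0)
        assert s.percentages[Category.EXTERNAL_GENTLE] == pytest.approx(25.0)

    def test_single_category_is_hundred_percent(self):
        s = self._summary(7, 0, 0)
        assert s.percentages[Category.INTERNAL] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        s = self._summary(13, 7, 3, extra=[Category.EXCLUDED_BOTH] * 4)
        assert sum(s.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_excluded_cells_not_in_numerator_or_denominator(self):
        with_excluded = self._summary(10, 5, 5, extra=[Category.EXCLUDED_BOTH] * 9)
        without = self._summary(10, 5, 5)
        assert with_excluded.percentages == without.percentages
        assert with_excluded.n_responders == 20

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="denominator"):
            self._summary(0, 0, 0, extra=[Category.EXCLUDED_BOTH] * 3)


class TestCompareGroups:
    def _sum(self, i, n, g, group=""):
        return ProportionSummary(
            group=group,
            counts={
                Category.INTERNAL: i,
                Category.EXTERNAL_NOXIOUS: n,
                Category.EXTERNAL_GENTLE: g,
            },
            n_total_cells=i + n + g,
        )

    def test_identical_groups_give_zero(self):
        res = compare_groups(self._sum(10, 10, 10), self._sum(10, 10, 10))
        assert res["chi2"] == 0.0 and res["p"] == 1.0 and res["dof"] == 2.0

    def test_matches_textbook_formula(self):
        res = compare_groups(self._sum(20, 5, 25), self._sum(2, 18, 10))
        expected = brute_force_chi2([[20, 5, 25], [2, 18, 10]])
        assert res["chi2"] == pytest.approx(expected, abs=1e-9)
        assert res["dof"] == 2.0

    def test_all_small_tables_match_oracle(self):
        """Exhaustive-ish sweep of small 2x3 tables against sum (O-E)^2/E."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.integers(0, 31, size=3)
            b = rng.integers(0, 31, size=3)
            if (a + b == 0).any() or a.sum() == 0 or b.sum() == 0:
                continue
            res = compare_groups(self._sum(*a), self._sum(*b))
            assert res["chi2"] == pytest.approx(brute_force_chi2([a, b]), abs=1e-9)

    def test_empty_category_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = compare_groups(self._sum(10, 0, 5), self._sum(3, 0, 12))
        assert res["dof"] == 1.0

    def test_no_continuity_correction_on_2x2(self):
        """Even when a dropped category reduces the table to 2x2 (where
        scipy would apply Yates by default), the statistic stays the plain
        Pearson sum (O-E)^2/E."""
        with pytest.warns(UserWarning, match="dropped"):
            res = compare_groups(self._sum(12, 0, 5), self._sum(4, 0, 16))
        table = [[12, 5], [4, 16]]
        assert res["chi2"] == pytest.approx(brute_force_chi2(table), abs=1e-9)
        yates = chi2_contingency(np.array(table), correction=True).statistic
        assert abs(res["chi2"] - yates) > 0.1


class TestPlantedClassRecovery:
    def test_noise_free_session_recovers_every_class(self, default_schedule):
        """On noiseless traces every non-excluded cell classifies to its
        planted class and every planted exclusion class is excluded."""
        counts = {cls: 2 for cls in CellClass}
        cells = generate_cells(counts, image_shape=(128, 128), seed=21)
        dff_vals = cell_traces(cells, default_schedule)
        from drgcal import compute_dff

        tm = TraceMatrix(
            values=dff_vals,
            cell_ids=tuple(c.cell_id for c in cells),
            frame_rate_hz=5.0,
            episode_boundaries=default_schedule.episode_starts,
            stage=TraceStage.CORRECTED,
        )
        dff = compute_dff(tm, default_schedule)
        table = call_responders(dff, default_schedule)
        flags = flag_exclusions(dff, table, None, default_schedule)
        expected = {
            CellClass.INTERNAL_ONLY: Category.INTERNAL,
            CellClass.EXTERNAL_GENTLE: Category.EXTERNAL_GENTLE,
            CellClass.EXTERNAL_NOXIOUS_ONLY: Category.EXTERNAL_NOXIOUS,
            CellClass.BOTH: Category.EXCLUDED_BOTH,
            CellClass.SILENT: Category.NONRESPONDER,
            CellClass.SPONTANEOUS: Category.EXCLUDED_SPONTANEOUS,
            CellClass.PERSISTENT: Category.EXCLUDED_PERSISTENT,
        }
        for cell, cls in zip(cells, classify_cells(table, flags, default_schedule)):
            assert cls.category is expected[cell.planted_class], cell.planted_class


def test_blinded_equivalence(default_schedule):
    """Shuffled, de-identified traces yield identical category proportions."""
    cells = generate_cells(image_shape=(128, 128), seed=13)
    dff_vals = cell_traces(cells, default_schedule)
    from drgcal import compute_dff

    tm = TraceMatrix(
        values=dff_vals,
        cell_ids=tuple(c.cell_id for c in cells),
        frame_rate_hz=5.0,
        episode_boundaries=default_schedule.episode_starts,
        stage=TraceStage.CORRECTED,
    )
    dff = compute_dff(tm, default_schedule)
    table = call_responders(dff, default_schedule)
    flags = flag_exclusions(dff, table, None, default_schedule)
    labeled = responder_proportions(classify_cells(table, flags, default_schedule))
    blinded = blinded_proportions(dff, default_schedule, seed=5)
    assert blinded.percentages == labeled.percentages
    assert blinded.count_vector().tolist() == labeled.count_vector().tolist()


@given(st.integers(min_value=1, max_value=19))
@settings(max_examples=19, deadline=None, derandomize=True)
def test_threshold_monotonicity_property(default_schedule, thr):
    """Included-responder totals never increase when the threshold rises."""
    rng = np.random.default_rng(17)
    vals = np.zeros((25, default_schedule.total_frames))
    for i, ep in enumerate(default_schedule.episodes):
        onset = default_schedule.episode_starts[i] + ep.onset_frame
        vals[:, onset + 3] = rng.uniform(0, 30, size=25)
    dff = TraceMatrix(
        values=vals, cell_ids=tuple(range(1, 26)), frame_rate_hz=5.0,
        episode_boundaries=default_schedule.episode_starts, stage=TraceStage.DFF,
    )
    lo = call_responders(dff, default_schedule, float(thr))
    hi = call_responders(dff, default_schedule, float(thr) + 1.0)
    # per-episode responder calls and cells-with-any-response are monotone;
    # the included-responder total is not (the both-site exclusion can
    # release a cell back into the pool as the threshold rises)
    assert hi.is_responder.sum() <= lo.is_responder.sum()
    assert (hi.is_responder & ~lo.is_responder).sum() == 0
    assert hi.is_responder.any(axis=1).sum() <= lo.is_responder.any(axis=1).sum()
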