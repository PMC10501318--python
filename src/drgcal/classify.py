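"""Responder calling, exclusion rules, category assignment, group comparison.

A cell is a responder to an episode if its peak percent dF/F in the response
window strictly exceeds the activation threshold (default 5%).  Cells with
spontaneous baseline activity, cells that stay active for the rest of the
session after a stimulus, and overlapping ROIs are excluded; cells responding
to both internal and external stimulation are excluded as likely movement
artifacts at the anal boundary.  Remaining responders fall into three
categories — Internal (colonic brush/balloon), External gentle (air puff
and/or skin brush, even if they also respond to pinch) and External noxious
(pinch only) — which are pooled to 100% of responder neurons, and two groups
of pooled proportions are compared with a Pearson chi-square test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .protocol import EpisodeSchedule, GENTLE_STIMULI, Site, Stimulus
from .traces import RoiSet, TraceMatrix, TraceStage

#: Activation threshold (percent dF/F), exceeded strictly.
DEFAULT_THRESHOLD_PCT = 5.0


class Category(str, enum.Enum):
    INTERNAL = "internal"
    EXTERNAL_NOXIOUS = "external_noxious"
    EXTERNAL_GENTLE = "external_gentle"
    EXCLUDED_BOTH = "excluded_both"
    EXCLUDED_SPONTANEOUS = "excluded_spontaneous"
    EXCLUDED_PERSISTENT = "excluded_persistent"
    EXCLUDED_OVERLAP = "excluded_overlap"
    NONRESPONDER = "nonresponder"


#: The three categories that enter the pooled-responder denominator.
RESPONDER_CATEGORIES = (
    Category.INTERNAL,
    Category.EXTERNAL_NOXIOUS,
    Category.EXTERNAL_GENTLE,
)


class ExclusionFlag(str, enum.Enum):
    OVERLAP = "overlap"
    SPONTANEOUS = "spontaneous"
    PERSISTENT = "persistent"


@dataclass(frozen=True)
class ResponderTable:
    """Per cell x episode peak dF/F and the strict-threshold responder call."""

    cell_ids: tuple[int, ...]
    peak_dff: np.ndarray  # cells x episodes, percent
    is_responder: np.ndarray  # cells x episodes, bool
    threshold_pct: float

    def to_frame(self) -> pd.DataFrame:
        n, e = self.peak_dff.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, e),
                "episode": np.tile(np.arange(e), n),
                "peak_dff": self.peak_dff.ravel(),
                "is_responder": self.is_responder.ravel(),
            }
        )


@dataclass(frozen=True)
class CellClassification:
    cell_id: int
    category: Category
    per_episode_responder: tuple[bool, ...]
    peak_dff: float  # session maximum, percent


@dataclass(frozen=True)
class ProportionSummary:
    """Pooled-responder category counts and percentages for one group."""

    group: str
    counts: dict[Category, int]
    n_total_cells: int

    @property
    def n_responders(self) -> int:
        return sum(self.counts.get(c, 0) for c in RESPONDER_CATEGORIES)

    @property
    def percentages(self) -> dict[Category, float]:
        n = self.n_responders
        return {c: 100.0 * self.counts.get(c, 0) / n for c in RESPONDER_CATEGORIES}

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(c, 0) for c in RESPONDER_CATEGORIES])

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "group": self.group,
                "category": [c.value for c in RESPONDER_CATEGORIES],
                "count": [self.counts.get(c, 0) for c in RESPONDER_CATEGORIES],
                "percent": [pct[c] for c in RESPONDER_CATEGORIES],
            }
        )


def call_responders(
    dff: TraceMatrix,
    schedule: EpisodeSchedule,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> ResponderTable:
    """Peak dF/F per episode over [onset, episode end) and the strict call.

    A cell responds to an episode iff its peak is strictly greater than
    ``threshold_pct`` (dF/F > threshold; a peak exactly at the threshold is
    not a response).
    """
    if dff.stage is not TraceStage.DFF:
        raise ValueError("call_responders requires dF/F-stage traces")
    if threshold_pct <= 0:
        raise ValueError(f"threshold_pct must be > 0, got {threshold_pct}")
    if schedule.total_frames != dff.n_frames:
        raise ValueError(
            f"schedule covers {schedule.total_frames} frames but traces have "
            f"{dff.n_frames}"
        )
    peaks = np.empty((dff.n_cells, schedule.n_episodes))
    for i, ep in enumerate(schedule.episodes):
        start = schedule.episode_starts[i]
        window = dff.values[:, start + ep.onset_frame : start + ep.n_frames]
        peaks[:, i] = window.max(axis=1)
    return ResponderTable(
        cell_ids=dff.cell_ids,
        peak_dff=peaks,
        is_responder=peaks > threshold_pct,
        threshold_pct=threshold_pct,
    )


def flag_exclusions(
    dff: TraceMatrix,
    responders: ResponderTable,
    rois: RoiSet | None,
    schedule: EpisodeSchedule,
    spontaneous_consecutive_frames: int = 3,
    persistent_fraction: float = 0.8,
) -> dict[int, ExclusionFlag]:
    """Flag cells to exclude before category assignment.

    SPONTANEOUS: dF/F above threshold for >= ``spontaneous_consecutive_frames``
    consecutive frames inside any episode's baseline window.  PERSISTENT:
    after the onset of the cell's first responding episode, dF/F stays above
    threshold in >= ``persistent_fraction`` of the remaining session frames.
    OVERLAP: the footprint shares a pixel with another label (requires the
    ROI construction record).  When several flags apply, OVERLAP wins over
    SPONTANEOUS over PERSISTENT.
    """
    if responders.cell_ids != dff.cell_ids:
        raise ValueError("responder table and traces disagree on cell ids")
    thr = responders.threshold_pct
    flags: dict[int, ExclusionFlag] = {}

    overlapping = rois.overlapping_labels() if rois is not None else set()

    for k, cell_id in enumerate(dff.cell_ids):
        if cell_id in overlapping:
            flags[cell_id] = ExclusionFlag.OVERLAP
            continue
        trace = dff.values[k]

        spontaneous = False
        for i, ep in enumerate(schedule.episodes):
            start = schedule.episode_starts[i]
            base = trace[start : start + ep.baseline_frames] > thr
            if _longest_run(base) >= spontaneous_consecutive_frames:
                spontaneous = True
                break
        if spontaneous:
            flags[cell_id] = ExclusionFlag.SPONTANEOUS
            continue

        responding = np.nonzero(responders.is_responder[k])[0]
        if responding.size:
            first = responding[0]
            onset = (
                schedule.episode_starts[first]
                + schedule.episodes[first].onset_frame
            )
            rest = trace[onset:] > thr
            if rest.size and rest.mean() >= persistent_fraction:
                flags[cell_id] = ExclusionFlag.PERSISTENT
    return flags


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def classify_cells(
    responders: ResponderTable,
    exclusion_flags: dict[int, ExclusionFlag],
    schedule: EpisodeSchedule,
) -> list[CellClassification]:
    """Assign each cell exactly one category.

    Precedence: exclusion flags first; then EXCLUDED_BOTH for cells with at
    least one internal-site and one external-site response; then INTERNAL
    for internal-only responders; EXTERNAL_GENTLE for any puff or skin-brush
    response (pinch co-response does not demote them); EXTERNAL_NOXIOUS for
    pinch-only responders; NONRESPONDER otherwise.
    """
    sites = []
    for ep in schedule.episodes:
        if ep.stimulus.site not in (Site.INTERNAL, Site.EXTERNAL):
            raise ValueError(f"unknown stimulus site for {ep.stimulus.name}")
        sites.append(ep.stimulus.site)
    sites_arr = np.array([s is Site.INTERNAL for s in sites])
    gentle_arr = np.array(
        [ep.stimulus.name in GENTLE_STIMULI for ep in schedule.episodes]
    )
    pinch_arr = np.array(
        [ep.stimulus.name is Stimulus.PINCH for ep in schedule.episodes]
    )

    _FLAG_TO_CATEGORY = {
        ExclusionFlag.OVERLAP: Category.EXCLUDED_OVERLAP,
        ExclusionFlag.SPONTANEOUS: Category.EXCLUDED_SPONTANEOUS,
        ExclusionFlag.PERSISTENT: Category.EXCLUDED_PERSISTENT,
    }

    out: list[CellClassification] = []
    for k, cell_id in enumerate(responders.cell_ids):
        calls = responders.is_responder[k]
        peak = float(responders.peak_dff[k].max())
        if cell_id in exclusion_flags:
            cat = _FLAG_TO_CATEGORY[exclusion_flags[cell_id]]
        elif not calls.any():
            cat = Category.NONRESPONDER
        elif (calls & sites_arr).any() and (calls & ~sites_arr).any():
            cat = Category.EXCLUDED_BOTH
        elif (calls & sites_arr).any():
            cat = Category.INTERNAL
        elif (calls & gentle_arr).any():
            cat = Category.EXTERNAL_GENTLE
        elif (calls & pinch_arr).any():
            cat = Category.EXTERNAL_NOXIOUS
        else:  # responded only to an external stimulus that is neither
            cat = Category.EXTERNAL_GENTLE
        out.append(
            CellClassification(
                cell_id=cell_id,
                category=cat,
                per_episode_responder=tuple(bool(c) for c in calls),
                peak_dff=peak,
            )
        )
    return out


#: Category a planted synthetic cell of each class should land in when the
#: pipeline recovers it (overlap-planted cells map to EXCLUDED_OVERLAP
#: regardless of class).
EXPECTED_CATEGORY = {
    "internal_only": Category.INTERNAL,
    "external_gentle": Category.EXTERNAL_GENTLE,
    "external_noxious_only": Category.EXTERNAL_NOXIOUS,
    "both": Category.EXCLUDED_BOTH,
    "silent": Category.NONRESPONDER,
    "spontaneous": Category.EXCLUDED_SPONTANEOUS,
    "persistent": Category.EXCLUDED_PERSISTENT,
}


def recovery_rate(cells, classifications: list[CellClassification]) -> dict:
    """Score classifications against planted ground truth.

    Returns counts of non-excluded planted cells recovered to their planted
    category, plus an all-cells tally (excluded planted classes count as
    recovered when any exclusion fires for them).
    """
    by_id = {c.cell_id: c for c in classifications}
    n_nonexcluded = correct_nonexcluded = 0
    n_all = correct_all = 0
    excluded_cats = {
        Category.EXCLUDED_BOTH,
        Category.EXCLUDED_SPONTANEOUS,
        Category.EXCLUDED_PERSISTENT,
        Category.EXCLUDED_OVERLAP,
    }
    for cell in cells:
        got = by_id[cell.cell_id].category
        if getattr(cell, "planted_overlap", False):
            expected = Category.EXCLUDED_OVERLAP
        else:
            expected = EXPECTED_CATEGORY[cell.planted_class.value]
        n_all += 1
        if expected in excluded_cats:
            correct_all += got in excluded_cats
        else:
            n_nonexcluded += 1
            correct_nonexcluded += got is expected
            correct_all += got is expected
    return {
        "n_nonexcluded": n_nonexcluded,
        "correct_nonexcluded": correct_nonexcluded,
        "n_all": n_all,
        "correct_all": correct_all,
    }


def responder_proportions(
    classifications: list[CellClassification], group: str = ""
) -> ProportionSummary:
    """Pool included responders to 100% and report category shares.

    Excluded cells and non-responders enter neither numerator nor
    denominator.

    Raises
    ------
    ValueError
        If no included responder remains (empty denominator).
    """
    counts: dict[Category, int] = {}
    for c in classifications:
        counts[c.category] = counts.get(c.category, 0) + 1
    n_resp = sum(counts.get(c, 0) for c in RESPONDER_CATEGORIES)
    if n_resp == 0:
        raise ValueError(
            "no included responders: the pooled-responder denominator is empty"
        )
    return ProportionSummary(
        group=group, counts=counts, n_total_cells=len(classifications)
    )


def compare_groups(
    summary_a: ProportionSummary, summary_b: ProportionSummary
) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on the 2 x 3 table of
    pooled-responder category counts; returns chi2, dof and p.

    A category empty in both groups is dropped (with a warning) and the
    degrees of freedom reduced accordingly.
    """
    table = np.vstack([summary_a.count_vector(), summary_b.count_vector()])
    keep = table.sum(axis=0) > 0
    if not keep.all():
        dropped = [
            c.value for c, k in zip(RESPONDER_CATEGORIES, keep) if not k
        ]
        warnings.warn(
            f"categories empty in both groups dropped from the test: {dropped}",
            stacklevel=2,
        )
        table = table[:, keep]
    if np.array_equal(table[0], table[1]):
        # identical groups: chi2 is exactly 0 by symmetry
        return {"chi2": 0.0, "dof": float(table.shape[1] - 1), "p": 1.0}
    res = chi2_contingency(table, correction=False)
    return {"chi2": float(res.statistic), "dof": float(res.dof), "p": float(res.pvalue)}


def blinded_proportions(
    dff: TraceMatrix,
    schedule: EpisodeSchedule,
    rois: RoiSet | None = None,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    seed: int = 0,
) -> ProportionSummary:
    """Reproducibility harness: de-identify and shuffle the traces, then
    classify.  Category proportions must match the labeled run, mirroring the
    blinded-vs-unblinded analyst check."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dff.n_cells)
    anon = TraceMatrix(
        values=dff.values[perm],
        cell_ids=tuple(range(1, dff.n_cells + 1)),  # identities hidden
        frame_rate_hz=dff.frame_rate_hz,
        episode_boundaries=dff.episode_boundaries,
        stage=dff.stage,
    )
    overlapping = rois.overlapping_labels() if rois is not None else set()
    responders = call_responders(anon, schedule, threshold_pct)
    flags = flag_exclusions(anon, responders, None, schedule)
    # carry overlap flags through the permutation by position
    for pos, orig_idx in enumerate(perm):
        orig_id = dff.cell_ids[orig_idx]
        if orig_id in overlapping:
            flags[anon.cell_ids[pos]] = ExclusionFlag.OVERLAP
    cls = classify_cells(responders, flags, schedule)
    return responder_proportions(cls, group="blinded")
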