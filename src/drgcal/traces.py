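"""ROI trace extraction, annulus (donut) background correction, percent dF/F.

Pipeline order: mean-over-footprint raw traces, subtraction of the mean of a
donut-shaped annulus surrounding each ROI (removes out-of-focus and surround
contamination; exact for spatially uniform backgrounds), then percent dF/F
against a per-episode baseline, with episodes concatenated so each row tracks
one neuron across the whole session.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .protocol import EpisodeSchedule
from .synthetic import GroundTruthCell, MovieStack


class RoiError(ValueError):
    """ROI geometry problem (empty footprint or annulus)."""


class DffError(ValueError):
    """Non-positive baseline fluorescence; affected cells are unusable."""

    def __init__(self, offenders: list[tuple[int, int]]):
        self.offenders = offenders
        super().__init__(
            "baseline F0 <= 0 for (cell_id, episode) pairs "
            f"{offenders}; these cells must be excluded, not zeroed"
        )


@dataclass(frozen=True)
class RoiSet:
    """Integer-labeled cell footprints with annulus geometry.

    ``label_image`` assigns each pixel to one cell (0 = background).  When
    footprints may overlap, ``footprints`` preserves the construction record
    (cell_id -> (rows, cols)); traces are read from the true footprints and
    overlaps can be detected, which a flat label image alone cannot encode.
    Annulus defaults (1 px gap, 3 px width) are a conventional choice.
    """

    label_image: np.ndarray
    annulus_gap_px: int = 1
    annulus_width_px: int = 3
    footprints: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.label_image.ndim != 2:
            raise RoiError("label image must be 2-D")
        if self.label_image.min() < 0:
            raise RoiError("labels must be non-negative integers")
        if self.annulus_gap_px < 0 or self.annulus_width_px < 1:
            raise RoiError("annulus gap must be >= 0 and width >= 1")

    @classmethod
    def from_cells(
        cls,
        cells: list[GroundTruthCell],
        image_shape: tuple[int, int],
        annulus_gap_px: int = 1,
        annulus_width_px: int = 3,
    ) -> "RoiSet":
        label = np.zeros(image_shape, dtype=np.int32)
        footprints: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for c in cells:
            label[c.rows, c.cols] = c.cell_id
            footprints[c.cell_id] = (c.rows.copy(), c.cols.copy())
        return cls(
            label_image=label,
            annulus_gap_px=annulus_gap_px,
            annulus_width_px=annulus_width_px,
            footprints=footprints,
        )

    @property
    def labels(self) -> tuple[int, ...]:
        if self.footprints is not None:
            return tuple(sorted(self.footprints))
        vals = np.unique(self.label_image)
        return tuple(int(v) for v in vals if v > 0)

    def footprint_pixels(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        if self.footprints is not None:
            return self.footprints[label]
        rows, cols = np.nonzero(self.label_image == label)
        return rows, cols

    def footprint_mask(self, label: int) -> np.ndarray:
        mask = np.zeros(self.label_image.shape, dtype=bool)
        rows, cols = self.footprint_pixels(label)
        mask[rows, cols] = True
        return mask

    def any_labeled_mask(self) -> np.ndarray:
        """Pixels belonging to ANY cell; all are excluded from every annulus."""
        mask = self.label_image > 0
        if self.footprints is not None:
            for rows, cols in self.footprints.values():
                mask[rows, cols] = True
        return mask

    def annulus_mask(self, label: int) -> np.ndarray:
        """Donut around ``label``: (footprint ⊕ gap+width) − (footprint ⊕ gap)
        minus every labeled pixel."""
        fp = self.footprint_mask(label)
        outer = binary_dilation(
            fp, structure=disk(self.annulus_gap_px + self.annulus_width_px)
        )
        inner = (
            binary_dilation(fp, structure=disk(self.annulus_gap_px))
            if self.annulus_gap_px > 0
            else fp
        )
        return outer & ~inner & ~self.any_labeled_mask()

    def overlapping_labels(self) -> set[int]:
        """Labels whose footprints share at least one pixel (needs the
        construction record; a flat label image cannot overlap)."""
        if self.footprints is None:
            return set()
        H, W = self.label_image.shape
        counts = np.zeros(H * W, dtype=np.int32)
        for rows, cols in self.footprints.values():
            counts[rows * W + cols] += 1
        shared = counts > 1
        out: set[int] = set()
        for lab, (rows, cols) in self.footprints.items():
            if shared[rows * W + cols].any():
                out.add(lab)
        return out


class TraceStage(str, enum.Enum):
    RAW = "raw"
    CORRECTED = "corrected"
    DFF = "dff"  # percent units


@dataclass(frozen=True)
class TraceMatrix:
    """Cells x frames traces at a given processing stage."""

    values: np.ndarray
    cell_ids: tuple[int, ...]
    frame_rate_hz: float
    episode_boundaries: tuple[int, ...]
    stage: TraceStage

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be cells x frames")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.cell_ids)} cell ids"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def row(self, cell_id: int) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, frame, value."""
        n, T = self.values.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, T),
                "frame": np.tile(np.arange(T), n),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_traces(movie: MovieStack, rois: RoiSet) -> TraceMatrix:
    """Mean-over-footprint raw fluorescence trace per labeled cell."""
    if rois.label_image.shape != movie.frame_shape:
        raise RoiError(
            f"label image {rois.label_image.shape} does not match movie "
            f"frames {movie.frame_shape}"
        )
    labels = rois.labels
    if not labels:
        raise RoiError("label image contains no ROIs (no label > 0)")
    T = movie.n_frames
    H, W = movie.frame_shape
    flat = movie.data.reshape(T, H * W)
    values = np.empty((len(labels), T))
    empty: list[int] = []
    for k, lab in enumerate(labels):
        rows, cols = rois.footprint_pixels(lab)
        if rows.size == 0:
            empty.append(lab)
            continue
        values[k] = flat[:, rows * W + cols].mean(axis=1)
    if empty:
        raise RoiError(f"empty footprints for labels {empty}")
    return TraceMatrix(
        values=values,
        cell_ids=labels,
        frame_rate_hz=movie.frame_rate_hz,
        episode_boundaries=tuple(movie.episode_boundaries),
        stage=TraceStage.RAW,
    )


def annulus_correct(
    movie: MovieStack, rois: RoiSet, neuropil_scale: float = 1.0
) -> TraceMatrix:
    """Subtract each cell's donut-annulus mean trace from its raw trace.

    The annulus is the footprint dilated by gap+width minus the footprint
    dilated by gap, with every labeled pixel removed so neighbouring cells
    never contaminate the correction.  ``neuropil_scale`` multiplies the
    subtracted trace (1.0 = direct subtraction, the default).
    """
    raw = extract_traces(movie, rois)
    T = movie.n_frames
    H, W = movie.frame_shape
    flat = movie.data.reshape(T, H * W)
    corrected = np.empty_like(raw.values)
    for k, lab in enumerate(raw.cell_ids):
        ann = rois.annulus_mask(lab)
        n_ann = int(ann.sum())
        if n_ann == 0:
            raise RoiError(
                f"annulus for label {lab} is empty (crowded field or image "
                "edge); widen annulus_width_px or reduce the gap"
            )
        rows, cols = np.nonzero(ann)
        neuropil = flat[:, rows * W + cols].mean(axis=1)
        corrected[k] = raw.values[k] - neuropil_scale * neuropil
    return TraceMatrix(
        values=corrected,
        cell_ids=raw.cell_ids,
        frame_rate_hz=raw.frame_rate_hz,
        episode_boundaries=raw.episode_boundaries,
        stage=TraceStage.CORRECTED,
    )


def compute_dff(traces: TraceMatrix, schedule: EpisodeSchedule) -> TraceMatrix:
    """Percent dF/F with a per-episode baseline.

    Within each episode, F0 is each cell's mean fluorescence over that
    episode's baseline frames and dF/F(t) = 100 * (F(t) - F0) / F0.

    Raises
    ------
    DffError
        If any cell-episode baseline is non-positive; the affected cells
        cannot be normalized and must be excluded upstream.
    """
    if traces.stage is TraceStage.DFF:
        raise ValueError("traces are already at the dF/F stage")
    if schedule.total_frames != traces.n_frames:
        raise ValueError(
            f"schedule covers {schedule.total_frames} frames but traces have "
            f"{traces.n_frames}"
        )
    out = np.empty_like(traces.values, dtype=float)
    offenders: list[tuple[int, int]] = []
    for i, ep in enumerate(schedule.episodes):
        sl = schedule.episode_slice(i)
        block = traces.values[:, sl]
        f0 = block[:, : ep.baseline_frames].mean(axis=1)
        bad = np.nonzero(f0 <= 0)[0]
        offenders.extend((traces.cell_ids[b], i) for b in bad)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, sl] = 100.0 * (block - f0[:, None]) / f0[:, None]
    if offenders:
        raise DffError(offenders)
    return TraceMatrix(
        values=out,
        cell_ids=traces.cell_ids,
        frame_rate_hz=traces.frame_rate_hz,
        episode_boundaries=schedule.episode_starts,
        stage=TraceStage.DFF,
    )


def concatenate_episodes(per_episode: list[TraceMatrix]) -> TraceMatrix:
    """Concatenate per-episode trace matrices in protocol order.

    All inputs must share the cell set and processing stage; episode starts
    are recorded as boundary markers (the inter-episode pauses are not data).
    """
    if not per_episode:
        raise ValueError("nothing to concatenate")
    first = per_episode[0]
    for m in per_episode[1:]:
        if m.cell_ids != first.cell_ids:
            raise ValueError(
                f"cell sets differ: {len(m.cell_ids)} vs {len(first.cell_ids)} cells"
            )
        if m.stage is not first.stage:
            raise ValueError(f"stages differ: {m.stage} vs {first.stage}")
        if m.frame_rate_hz != first.frame_rate_hz:
            raise ValueError("frame rates differ")
    boundaries, t = [], 0
    for m in per_episode:
        boundaries.append(t)
        t += m.n_frames
    return TraceMatrix(
        values=np.hstack([m.values for m in per_episode]),
        cell_ids=first.cell_ids,
        frame_rate_hz=first.frame_rate_hz,
        episode_boundaries=tuple(boundaries),
        stage=first.stage,
    )
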