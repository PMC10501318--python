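"""File-format plumbing: TIFF movies and label images, trace CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocol import EpisodeSchedule
from .synthetic import MovieStack
from .traces import TraceMatrix, TraceStage


def write_movie_tiff(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as a multi-page 32-bit float TIFF (one page per frame).
    Episode boundaries travel in the sidecar schedule JSON, not the TIFF."""
    tifffile.imwrite(Path(path), movie.data.astype(np.float32))


def read_movie_tiff(
    path: str | Path, schedule: EpisodeSchedule
) -> MovieStack:
    """Read a registered multi-page TIFF as a movie stack; frame count must
    match the schedule."""
    data = tifffile.imread(Path(path)).astype(float)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != schedule.total_frames:
        raise ValueError(
            f"{path}: movie has {data.shape[0]} frames but the schedule "
            f"covers {schedule.total_frames}"
        )
    return MovieStack(
        data=data,
        frame_rate_hz=schedule.frame_rate_hz,
        episode_boundaries=schedule.episode_starts,
    )


def write_label_image(label: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), label.astype(np.int32))


def read_label_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(np.int32)
    from imageio.v3 import imread

    return imread(path).astype(np.int32)


def read_traces_csv(
    path: str | Path,
    frame_rate_hz: float,
    episode_boundaries: tuple[int, ...],
    stage: TraceStage,
) -> TraceMatrix:
    """Read a long-format (cell_id, frame, value) CSV back into a matrix."""
    df = pd.read_csv(path)
    wide = df.pivot(index="cell_id", columns="frame", values="value").sort_index()
    return TraceMatrix(
        values=wide.to_numpy(dtype=float),
        cell_ids=tuple(int(c) for c in wide.index),
        frame_rate_hz=frame_rate_hz,
        episode_boundaries=episode_boundaries,
        stage=stage,
    )
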