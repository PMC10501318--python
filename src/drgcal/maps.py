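"""Visualization surfaces: pixelwise-SD activity maps and sorted heatmaps.

The spatial activity map is the per-pixel standard deviation of the movie
over all frames of the stimulation episodes of one site (external or
internal), highlighting the pixels whose fluorescence changed most.  The
heatmap layout orders included responders in category blocks (Internal,
External gentle, External noxious), descending by session-peak dF/F within
each block, with gap markers at episode boundaries for the inter-epoch
pauses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import Category, CellClassification, RESPONDER_CATEGORIES
from .protocol import EpisodeSchedule, Site
from .synthetic import MovieStack
from .traces import TraceMatrix, TraceStage

#: Heatmap block order (top to bottom).
BLOCK_ORDER = (
    Category.INTERNAL,
    Category.EXTERNAL_GENTLE,
    Category.EXTERNAL_NOXIOUS,
)


@dataclass(frozen=True)
class SpatialActivityMap:
    sd_image: np.ndarray  # H x W, >= 0
    pooled_site: Site
    episode_indices: tuple[int, ...]


@dataclass(frozen=True)
class HeatmapLayout:
    """Row order and block boundaries for a category-sorted dF/F heatmap."""

    row_order: tuple[int, ...]  # cell ids, top to bottom
    block_boundaries: dict[Category, tuple[int, int]]  # half-open row ranges
    episode_boundaries: tuple[int, ...]  # frame indices for gap markers

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, (lo, hi) in self.block_boundaries.items():
            for pos in range(lo, hi):
                rows.append(
                    {"row": pos, "cell_id": self.row_order[pos], "category": cat.value}
                )
        return pd.DataFrame(rows, columns=["row", "cell_id", "category"])


def sd_map(
    movie: MovieStack,
    schedule: EpisodeSchedule,
    site: Site,
    episode: int | None = None,
) -> SpatialActivityMap:
    """Per-pixel population SD (ddof=0) over the frames of one site's
    episodes, pooled; pass ``episode`` to restrict to a single episode."""
    if episode is not None:
        indices = [episode]
        if schedule.episodes[episode].stimulus.site is not site:
            raise ValueError(
                f"episode {episode} is not a {site.value}-site episode"
            )
    else:
        indices = schedule.episodes_of_site(site)
    if not indices:
        raise ValueError(f"schedule has no {site.value}-site episodes")
    frames = np.concatenate(
        [movie.data[schedule.episode_slice(i)] for i in indices], axis=0
    )
    return SpatialActivityMap(
        sd_image=frames.std(axis=0, ddof=0),
        pooled_site=site,
        episode_indices=tuple(indices),
    )


def sort_heatmap(
    dff: TraceMatrix, classifications: list[CellClassification]
) -> HeatmapLayout:
    """Category-block row order for the heatmap.

    Blocks follow Internal, External gentle, External noxious; excluded
    cells and non-responders are omitted.  Within a block, rows descend by
    session-peak dF/F, ties broken by ascending cell id.
    """
    if dff.stage is not TraceStage.DFF:
        raise ValueError("sort_heatmap requires dF/F-stage traces")
    by_id = {c.cell_id: c for c in classifications}
    missing = [cid for cid in dff.cell_ids if cid not in by_id]
    if missing:
        raise ValueError(f"no classification for cells {missing}")
    order: list[int] = []
    blocks: dict[Category, tuple[int, int]] = {}
    for cat in BLOCK_ORDER:
        members = [
            c for c in classifications
            if c.category is cat and c.cell_id in set(dff.cell_ids)
        ]
        members.sort(key=lambda c: (-c.peak_dff, c.cell_id))
        lo = len(order)
        order.extend(c.cell_id for c in members)
        blocks[cat] = (lo, len(order))
    return HeatmapLayout(
        row_order=tuple(order),
        block_boundaries=blocks,
        episode_boundaries=dff.episode_boundaries,
    )


def render_heatmap(
    dff: TraceMatrix,
    layout: HeatmapLayout,
    path: str | Path,
    vmin: float = -10.0,
    vmax: float = 50.0,
) -> None:
    """Write the sorted dF/F heatmap as a PNG with white gap lines at the
    episode boundaries (the unrecorded inter-epoch pauses)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [dff.row(cid) for cid in layout.row_order]
    img = np.vstack(rows) if rows else np.zeros((0, dff.n_frames))
    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(rows))))
    ax.imshow(img, aspect="auto", cmap="magma", vmin=vmin, vmax=vmax)
    for b in layout.episode_boundaries[1:]:
        ax.axvline(b - 0.5, color="white", lw=1.5)
    for cat, (lo, hi) in layout.block_boundaries.items():
        if hi > lo:
            ax.axhline(hi - 0.5, color="cyan", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("cell (sorted)")
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def save_sd_map(amap: SpatialActivityMap, path: str | Path) -> None:
    """Write the SD image as a 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), amap.sd_image.astype(np.float32))
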