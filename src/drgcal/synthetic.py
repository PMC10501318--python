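"""Ground-truthed synthetic sessions emulating the seven-episode protocol.

The generator plants cells of known response class (internal-only,
external-gentle, external-noxious-only, both-site, silent, spontaneously
active, persistently active), renders a GCaMP6f-like movie — step rise at
stimulus onset, exponential decay — over a spatially uniform drifting
background with Gaussian sensor noise, and records everything needed to score
the downstream pipeline: footprints, planted classes, amplitudes and baseline
levels.

Persistently active cells are rendered as a non-decaying staircase (a fresh
step at each subsequent episode onset) rather than a flat elevation: because
dF/F baselines are re-estimated per episode, a constant elevation would be
normalized away and the persistence detector could never see it.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .protocol import EpisodeSchedule, Site, Stimulus, generate_schedule


class CellClass(str, enum.Enum):
    """Planted response class of a synthetic cell."""

    INTERNAL_ONLY = "internal_only"
    EXTERNAL_GENTLE = "external_gentle"
    EXTERNAL_NOXIOUS_ONLY = "external_noxious_only"
    BOTH = "both"
    SILENT = "silent"
    SPONTANEOUS = "spontaneous"
    PERSISTENT = "persistent"


#: Default cell counts for a simulated session (a field of ~34 cells sits
#: inside the 10–50 neurons-per-animal range typical of these recordings).
DEFAULT_CELL_COUNTS: dict[CellClass, int] = {
    CellClass.INTERNAL_ONLY: 10,
    CellClass.EXTERNAL_GENTLE: 8,
    CellClass.EXTERNAL_NOXIOUS_ONLY: 4,
    CellClass.BOTH: 3,
    CellClass.SILENT: 5,
    CellClass.SPONTANEOUS: 2,
    CellClass.PERSISTENT: 2,
}

#: Per-class amplitude draw ranges (percent dF/F), reflecting the observed
#: spread: skin-evoked responses 5–60%, colonic responses 5–30%.
_AMPLITUDE_RANGES: dict[CellClass, tuple[float, float]] = {
    CellClass.INTERNAL_ONLY: (10.0, 30.0),
    CellClass.EXTERNAL_GENTLE: (10.0, 60.0),
    CellClass.EXTERNAL_NOXIOUS_ONLY: (10.0, 60.0),
    CellClass.BOTH: (10.0, 30.0),
    CellClass.SILENT: (0.0, 0.0),
    CellClass.SPONTANEOUS: (15.0, 30.0),
    CellClass.PERSISTENT: (15.0, 30.0),
}

#: Frame (relative to episode start) at which a spontaneous transient fires,
#: well inside the 40-frame baseline window.
_SPONTANEOUS_FRAME = 5


class PlacementError(RuntimeError):
    """The field is too small to place the requested cells without overlap."""


@dataclass(frozen=True)
class GroundTruthCell:
    """A planted cell: footprint pixels, class, amplitude, baseline level."""

    cell_id: int
    rows: np.ndarray  # footprint pixel rows
    cols: np.ndarray  # footprint pixel cols
    planted_class: CellClass
    transient_amplitude: float  # percent dF/F per responding episode
    baseline_level: float  # raw intensity units
    planted_overlap: bool = False

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


def generate_cells(
    n_per_class: dict[CellClass, int] | None = None,
    image_shape: tuple[int, int] = (256, 256),
    footprint_radius: int = 4,
    seed: int | None = None,
    amplitude_pct: float | None = None,
    baseline_range: tuple[float, float] = (80.0, 120.0),
    plant_overlap_pair: bool = False,
) -> list[GroundTruthCell]:
    """Place disk-footprint cells of the requested classes at random.

    Footprints are filled disks of ``footprint_radius`` placed by rejection
    sampling so that distinct cells never touch; ``plant_overlap_pair`` adds
    one deliberately overlapping pair for exercising the overlap exclusion.
    ``amplitude_pct`` forces a single amplitude for every responding cell;
    by default amplitudes are drawn per class from realistic ranges.
    Deterministic for a fixed ``seed``.

    Raises
    ------
    PlacementError
        If a non-overlapping placement cannot be found.
    """
    if n_per_class is None:
        n_per_class = DEFAULT_CELL_COUNTS
    rng = np.random.default_rng(seed)
    H, W = image_shape
    r = footprint_radius
    if H < 2 * r + 1 or W < 2 * r + 1:
        raise PlacementError(
            f"image {image_shape} cannot hold a radius-{r} footprint"
        )

    order: list[tuple[CellClass, bool]] = []
    for cls in CellClass:  # fixed class order keeps seeding reproducible
        for _ in range(int(n_per_class.get(cls, 0))):
            order.append((cls, False))
    if plant_overlap_pair:
        order.append((CellClass.INTERNAL_ONLY, True))
        order.append((CellClass.INTERNAL_ONLY, True))

    centers: list[tuple[int, int]] = []
    cells: list[GroundTruthCell] = []
    min_dist = 2 * r + 2  # no touching footprints unless planted
    for cell_id, (cls, is_overlap) in enumerate(order, start=1):
        if is_overlap and centers and cells and cells[-1].planted_overlap:
            # second member of the planted pair: offset by one radius
            pr, pc = centers[-1]
            cr, cc = pr, min(pc + r, W - r - 1)
        else:
            for _ in range(10_000):
                cr = int(rng.integers(r, H - r))
                cc = int(rng.integers(r, W - r))
                ok = all(
                    (cr - orr) ** 2 + (cc - occ) ** 2 >= min_dist**2
                    for orr, occ in centers
                )
                if ok:
                    break
            else:
                raise PlacementError(
                    f"could not place cell {cell_id} of {len(order)} in a "
                    f"{H}x{W} field without unplanted overlap"
                )
        rows, cols = draw_disk((cr, cc), r + 0.5, shape=(H, W))
        lo, hi = _AMPLITUDE_RANGES[cls]
        if cls is CellClass.SILENT:
            amp = 0.0
        elif amplitude_pct is not None:
            amp = float(amplitude_pct)
        else:
            amp = float(rng.uniform(lo, hi))
        baseline = float(rng.uniform(*baseline_range))
        centers.append((cr, cc))
        cells.append(
            GroundTruthCell(
                cell_id=cell_id,
                rows=rows,
                cols=cols,
                planted_class=cls,
                transient_amplitude=amp,
                baseline_level=baseline,
                planted_overlap=is_overlap,
            )
        )
    return cells


# -- signal model ----------------------------------------------------------


def responding_episodes(cls: CellClass, schedule: EpisodeSchedule) -> list[int]:
    """Episode indices in which a cell of the given class fires a transient."""
    internal = schedule.episodes_of_site(Site.INTERNAL)
    gentle = [
        i
        for i, ep in enumerate(schedule.episodes)
        if ep.stimulus.name in (Stimulus.PUFF, Stimulus.SKIN_BRUSH)
    ]
    pinch = [
        i
        for i, ep in enumerate(schedule.episodes)
        if ep.stimulus.name is Stimulus.PINCH
    ]
    external = schedule.episodes_of_site(Site.EXTERNAL)
    if cls is CellClass.INTERNAL_ONLY:
        return internal
    if cls is CellClass.EXTERNAL_GENTLE:
        return gentle
    if cls is CellClass.EXTERNAL_NOXIOUS_ONLY:
        return pinch
    if cls is CellClass.BOTH:
        out = []
        if external:
            out.append(external[0])
        if internal:
            out.append(internal[0])
        return out
    if cls is CellClass.PERSISTENT:
        # first response at the pinch (or the first episode if none); the
        # signal then persists through every later episode
        return pinch[:1] if pinch else [0]
    return []  # SILENT and SPONTANEOUS respond to no stimulus


def cell_signal(
    cls: CellClass, schedule: EpisodeSchedule, tau_s: float = 1.0
) -> np.ndarray:
    """Unit-amplitude activation s(t) over the concatenated session.

    The rendered fluorescence of a cell is
    ``baseline_level * (1 + amplitude/100 * s(t))``.  For transient classes
    s(t) steps to 1 at each responding onset and decays exponentially with
    time constant ``tau_s``; spontaneous cells fire one such transient during
    the first episode's baseline; persistent cells accumulate non-decaying
    unit steps at their first responding onset and every later episode onset.
    """
    T = schedule.total_frames
    t = np.arange(T, dtype=float)
    s = np.zeros(T)
    tau_frames = tau_s * schedule.frame_rate_hz
    starts = schedule.episode_starts

    def transient(onset: int) -> np.ndarray:
        out = np.zeros(T)
        out[onset:] = np.exp(-(t[onset:] - onset) / tau_frames)
        return out

    if cls is CellClass.SPONTANEOUS:
        s += transient(starts[0] + _SPONTANEOUS_FRAME)
    elif cls is CellClass.PERSISTENT:
        first = responding_episodes(cls, schedule)[0]
        for i in range(first, schedule.n_episodes):
            onset = starts[i] + schedule.episodes[i].onset_frame
            s[onset:] += 1.0  # non-decaying staircase
    else:
        for i in responding_episodes(cls, schedule):
            onset = starts[i] + schedule.episodes[i].onset_frame
            s += transient(onset)
    return s


def cell_traces(
    cells: list[GroundTruthCell],
    schedule: EpisodeSchedule,
    tau_s: float = 1.0,
) -> np.ndarray:
    """Noise-free cell-only fluorescence traces, cells x frames."""
    out = np.empty((len(cells), schedule.total_frames))
    for k, c in enumerate(cells):
        s = cell_signal(c.planted_class, schedule, tau_s=tau_s)
        out[k] = c.baseline_level * (1.0 + c.transient_amplitude / 100.0 * s)
    return out


@dataclass(frozen=True)
class MovieStack:
    """A T x H x W non-negative intensity stack with episode boundaries."""

    data: np.ndarray
    frame_rate_hz: float
    episode_boundaries: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T x H x W, got shape {self.data.shape}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def render_movie(
    cells: list[GroundTruthCell],
    schedule: EpisodeSchedule,
    image_shape: tuple[int, int] = (256, 256),
    background_level: float = 100.0,
    background_drift_amplitude: float = 0.0,
    drift_period_s: float = 20.0,
    noise_sd: float = 0.0,
    tau_s: float = 1.0,
    halo_sigma_px: float | None = None,
    seed: int | None = None,
) -> MovieStack:
    """Render a registered fluorescence movie from planted cells.

    The frame is the sum of (i) each cell's fluorescence on its footprint,
    (ii) a spatially uniform background with mean ``background_level`` and a
    sinusoidal drift of amplitude ``background_drift_amplitude`` (period
    ``drift_period_s``), and (iii) i.i.d. Gaussian noise of standard
    deviation ``noise_sd``, clipped at zero.  ``halo_sigma_px`` optionally
    smears cell signal into the surround (local contamination); it is off by
    default so that annulus subtraction is exact for the uniform background.
    Bit-reproducible for a fixed ``seed``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    H, W = image_shape
    T = schedule.total_frames
    t = np.arange(T, dtype=float)
    drift = background_drift_amplitude * np.sin(
        2.0 * np.pi * t / (drift_period_s * schedule.frame_rate_hz)
    )
    background = background_level + drift

    movie = np.broadcast_to(background[:, None, None], (T, H, W)).copy()
    if cells:
        cell_component = np.zeros((T, H, W))
        traces = cell_traces(cells, schedule, tau_s=tau_s)
        for c, trace in zip(cells, traces):
            if c.rows.size and (c.rows.max() >= H or c.cols.max() >= W):
                raise ValueError(f"cell {c.cell_id} footprint exceeds {image_shape}")
            cell_component[:, c.rows, c.cols] += trace[:, None]
        if halo_sigma_px:
            from scipy.ndimage import gaussian_filter

            cell_component = gaussian_filter(
                cell_component, sigma=(0.0, halo_sigma_px, halo_sigma_px)
            )
        movie += cell_component
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
    np.clip(movie, 0.0, None, out=movie)
    return MovieStack(
        data=movie,
        frame_rate_hz=schedule.frame_rate_hz,
        episode_boundaries=schedule.episode_starts,
    )


def simulate_session(
    seed: int | None = None,
    schedule: EpisodeSchedule | None = None,
    n_per_class: dict[CellClass, int] | None = None,
    image_shape: tuple[int, int] = (256, 256),
    footprint_radius: int = 4,
    amplitude_pct: float | None = None,
    background_level: float = 100.0,
    background_drift_amplitude: float = 5.0,
    noise_sd: float = 1.0,
    tau_s: float = 1.0,
    plant_overlap_pair: bool = False,
) -> tuple[list[GroundTruthCell], EpisodeSchedule, MovieStack]:
    """Convenience wrapper: schedule + cells + rendered movie in one call.

    Defaults define the standard simulated session: the seven-episode
    protocol on a 256x256 field, background 100 with a 5-unit slow drift and
    sensor noise of 1 unit (1% of background).
    """
    if schedule is None:
        schedule = generate_schedule()
    cells = generate_cells(
        n_per_class=n_per_class,
        image_shape=image_shape,
        footprint_radius=footprint_radius,
        seed=seed,
        amplitude_pct=amplitude_pct,
        plant_overlap_pair=plant_overlap_pair,
    )
    movie = render_movie(
        cells,
        schedule,
        image_shape=image_shape,
        background_level=background_level,
        background_drift_amplitude=background_drift_amplitude,
        noise_sd=noise_sd,
        tau_s=tau_s,
        seed=None if seed is None else seed + 1,
    )
    return cells, schedule, movie


# -- ground-truth serialization -------------------------------------------


def _rle_encode(rows: np.ndarray, cols: np.ndarray) -> list[list[int]]:
    """Run-length encode footprint pixels as [row, col_start, run] triples."""
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    runs: list[list[int]] = []
    for r, c in zip(rows.tolist(), cols.tolist()):
        if runs and runs[-1][0] == r and runs[-1][1] + runs[-1][2] == c:
            runs[-1][2] += 1
        else:
            runs.append([r, c, 1])
    return runs


def _rle_decode(runs: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    for r, c, n in runs:
        rows.extend([r] * n)
        cols.extend(range(c, c + n))
    return np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)


def write_ground_truth(cells: list[GroundTruthCell], path: str | Path) -> None:
    """Write planted cells (classes, amplitudes, RLE footprints) as JSON."""
    payload = [
        {
            "cell_id": c.cell_id,
            "planted_class": c.planted_class.value,
            "transient_amplitude": c.transient_amplitude,
            "baseline_level": c.baseline_level,
            "planted_overlap": c.planted_overlap,
            "footprint_rle": _rle_encode(c.rows, c.cols),
        }
        for c in cells
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> list[GroundTruthCell]:
    payload = json.loads(Path(path).read_text())
    cells = []
    for d in payload:
        rows, cols = _rle_decode(d["footprint_rle"])
        cells.append(
            GroundTruthCell(
                cell_id=int(d["cell_id"]),
                rows=rows,
                cols=cols,
                planted_class=CellClass(d["planted_class"]),
                transient_amplitude=float(d["transient_amplitude"]),
                baseline_level=float(d["baseline_level"]),
                planted_overlap=bool(d["planted_overlap"]),
            )
        )
    return cells


# -- fixtures for the GI quantification ratios -----------------------------


def generate_quant_fixtures(seed: int | None = None, n_samples: int = 8) -> dict:
    """Small tabular fixtures with their ground-truth ratios attached.

    Returns a dict with a gastric region-signal table, a stool wet/dry
    weight table, a binary nerve mask with an innervated-ganglia count, and a
    ``ground_truth`` entry holding every ratio computed at generation time
    (emptying %, water content %, nerve density, IGVE density).
    """
    rng = np.random.default_rng(seed)

    stomach = rng.uniform(1e7, 1e9, size=n_samples)
    emptied_frac = rng.uniform(0.05, 0.95, size=n_samples)
    rest = stomach * emptied_frac / (1.0 - emptied_frac)
    regions = pd.DataFrame(
        {
            "sample_id": [f"s{i+1}" for i in range(n_samples)],
            "stomach_signal": stomach,
            "rest_of_gut_signal": rest,
        }
    )

    wet = rng.uniform(20.0, 120.0, size=n_samples)  # mg
    water_frac = rng.uniform(0.3, 0.8, size=n_samples)
    dry = wet * (1.0 - water_frac)
    stools = pd.DataFrame(
        {
            "sample_id": [f"s{i+1}" for i in range(n_samples)],
            "wet_weight_mg": wet,
            "dry_weight_mg": dry,
            "width_mm": rng.uniform(1.5, 4.0, size=n_samples),
            "length_mm": rng.uniform(3.0, 9.0, size=n_samples),
        }
    )

    # binary nerve mask on an 80x80 px field (the 80 um x 80 um convention)
    mask = np.zeros((80, 80), dtype=bool)
    for _ in range(rng.integers(3, 8)):
        cr, cc = rng.integers(5, 75, size=2)
        rr, cc_ = draw_disk((cr, cc), rng.uniform(4, 12), shape=mask.shape)
        mask[rr, cc_] = True
    ganglia_count = int(rng.integers(0, 9))
    field_area = mask.size

    ground_truth = {
        "emptying_pct": (100.0 * rest / (stomach + rest)).tolist(),
        "retention_pct": (100.0 * stomach / (stomach + rest)).tolist(),
        "water_content_pct": (100.0 * (wet - dry) / wet).tolist(),
        "nerve_density": float(mask.sum() / field_area),
        "igve_density_per_px2": ganglia_count / field_area,
    }
    return {
        "regions": regions,
        "stools": stools,
        "nerve_mask": mask,
        "ganglia_count": ganglia_count,
        "field_area_px2": field_area,
        "ground_truth": ground_truth,
    }
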