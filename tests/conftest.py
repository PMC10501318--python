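import numpy as np
import pytest

from drgcal import (
    RoiSet,
    Stimulus,
    generate_cells,
    generate_schedule,
    render_movie,
)
from drgcal.synthetic import CellClass


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """Three-episode miniature protocol (one gentle, one pinch, one internal),
    8 s episodes with a 2 s baseline at 5 Hz."""
    return generate_schedule(
        frame_rate_hz=5.0,
        episode_s=8.0,
        baseline_s=2.0,
        stimuli=(Stimulus.PUFF, Stimulus.PINCH, Stimulus.BALLOON_INFLATE),
    )


@pytest.fixture
def small_session(short_schedule):
    """Noise-free 64x64 session with one cell per responding class."""
    counts = {
        CellClass.INTERNAL_ONLY: 1,
        CellClass.EXTERNAL_GENTLE: 1,
        CellClass.EXTERNAL_NOXIOUS_ONLY: 1,
        CellClass.SILENT: 1,
    }
    cells = generate_cells(
        counts, image_shape=(64, 64), footprint_radius=3, seed=7, amplitude_pct=20.0
    )
    movie = render_movie(
        cells,
        short_schedule,
        image_shape=(64, 64),
        background_level=50.0,
        background_drift_amplitude=4.0,
        noise_sd=0.0,
    )
    rois = RoiSet.from_cells(cells, (64, 64))
    return cells, short_schedule, movie, rois


# ---- independent brute-force oracles ------------------------------------


def brute_force_traces(movie_data, rois: RoiSet):
    """Per-pixel loop implementation of mean-over-footprint extraction."""
    labels = rois.labels
    T = movie_data.shape[0]
    out = np.zeros((len(labels), T))
    for k, lab in enumerate(labels):
        rows, cols = rois.footprint_pixels(lab)
        pix = list(zip(rows.tolist(), cols.tolist()))
        for t in range(T):
            out[k, t] = sum(movie_data[t, r, c] for r, c in pix) / len(pix)
    return out


def brute_force_annulus_correct(movie_data, rois: RoiSet):
    """Loop implementation of raw-minus-annulus-mean correction."""
    raw = brute_force_traces(movie_data, rois)
    T = movie_data.shape[0]
    out = np.zeros_like(raw)
    for k, lab in enumerate(rois.labels):
        ann = rois.annulus_mask(lab)
        pix = list(zip(*np.nonzero(ann)))
        for t in range(T):
            neuropil = sum(movie_data[t, r, c] for r, c in pix) / len(pix)
            out[k, t] = raw[k, t] - neuropil
    return out


def brute_force_sd(frames):
    """Two-pass per-pixel population standard deviation."""
    T, H, W = frames.shape
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            xs = frames[:, r, c]
            mu = sum(xs) / T
            out[r, c] = (sum((x - mu) ** 2 for x in xs) / T) ** 0.5
    return out


def brute_force_chi2(table):
    """Textbook Pearson chi-square: sum (O-E)^2 / E over the table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = row[i] * col[j] / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2
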