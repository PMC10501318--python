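"""Pipeline configuration: one YAML-serializable object drives every stage.

All protocol constants (frame rate, episode/baseline durations, threshold,
balloon pressures, puff durations) are defaults here, never hard-coded in
the stages, and the config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_CELL_COUNTS, CellClass


@dataclass
class PipelineConfig:
    # protocol constants
    frame_rate_hz: float = 5.0
    episode_s: float = 40.0
    baseline_s: float = 8.0
    threshold_pct: float = 5.0
    balloon_pressures_mmhg: list[int] = field(default_factory=lambda: [100, 150, 200])
    puff_durations_s: list[float] = field(default_factory=lambda: [0.2, 1.0, 3.0, 5.0])
    # annulus geometry and exclusion rules
    annulus_gap_px: int = 1
    annulus_width_px: int = 3
    neuropil_scale: float = 1.0
    spontaneous_consecutive_frames: int = 3
    persistent_fraction: float = 0.8
    # synthetic-session parameters
    image_shape: list[int] = field(default_factory=lambda: [256, 256])
    footprint_radius: int = 4
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {k.value: v for k, v in DEFAULT_CELL_COUNTS.items()}
    )
    amplitude_pct: float | None = None  # None: realistic per-class draws
    background_level: float = 100.0
    background_drift_amplitude: float = 5.0
    noise_sd: float = 1.0
    tau_s: float = 1.0
    plant_overlap_pair: bool = False
    # run control
    seed: int = 0
    save_movie: bool = False

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "episode_s", "baseline_s", "threshold_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.annulus_width_px < 1 or self.annulus_gap_px < 0:
            raise ValueError("annulus width must be >= 1 and gap >= 0")
        if not (0 < self.persistent_fraction <= 1):
            raise ValueError("persistent_fraction must be in (0, 1]")
        for k in self.n_per_class:
            CellClass(k)  # raises on unknown class names

    def cell_counts(self) -> dict[CellClass, int]:
        return {CellClass(k): v for k, v in self.n_per_class.items()}

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
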