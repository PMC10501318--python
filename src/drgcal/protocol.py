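"""Stimulation protocol: stimulus classes and the episode schedule.

The recording session consists of short imaging epochs ("episodes"), each
opening with a baseline period and followed by one mechanical stimulus.
External stimuli are applied to the perineal skin (air puff, gentle brush,
pinch); internal stimuli are applied inside the distal colon (soft brush
insertion/extraction, balloon insertion/inflation).  The default protocol is
seven episodes of 40 s recorded at 5 Hz (200 frames) with an 8 s (40-frame)
baseline, in the order: puff, skin brush, pinch, colon-brush insert,
colon-brush extract, balloon insert, balloon inflate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path


class Site(str, enum.Enum):
    """Where a stimulus is applied: perineal skin or inside the colon."""

    EXTERNAL = "external"
    INTERNAL = "internal"


class Stimulus(str, enum.Enum):
    PUFF = "puff"
    SKIN_BRUSH = "skin_brush"
    PINCH = "pinch"
    COLON_BRUSH_INSERT = "colon_brush_insert"
    COLON_BRUSH_EXTRACT = "colon_brush_extract"
    BALLOON_INSERT = "balloon_insert"
    BALLOON_INFLATE = "balloon_inflate"

    @property
    def site(self) -> Site:
        if self in _EXTERNAL_STIMULI:
            return Site.EXTERNAL
        return Site.INTERNAL


_EXTERNAL_STIMULI = frozenset(
    {Stimulus.PUFF, Stimulus.SKIN_BRUSH, Stimulus.PINCH}
)

#: Gentle external stimuli: a responder to any of these is "external gentle"
#: even if it also responds to the pinch.
GENTLE_STIMULI = frozenset({Stimulus.PUFF, Stimulus.SKIN_BRUSH})

#: Episode order of the standard seven-episode session.
DEFAULT_PROTOCOL: tuple[Stimulus, ...] = (
    Stimulus.PUFF,
    Stimulus.SKIN_BRUSH,
    Stimulus.PINCH,
    Stimulus.COLON_BRUSH_INSERT,
    Stimulus.COLON_BRUSH_EXTRACT,
    Stimulus.BALLOON_INSERT,
    Stimulus.BALLOON_INFLATE,
)

#: Balloon pressures (mmHg) and puff durations (s) used in the protocol;
#: carried as intensity labels, they do not alter schedule geometry.
BALLOON_PRESSURES_MMHG = (100, 150, 200)
PUFF_DURATIONS_S = (0.2, 1.0, 3.0, 5.0)


@dataclass(frozen=True)
class StimulusClass:
    """A stimulus with its application site and free-text intensity label."""

    name: Stimulus
    intensity_label: str = ""

    @property
    def site(self) -> Site:
        return self.name.site


@dataclass(frozen=True)
class Episode:
    """One imaging epoch: baseline frames, then a stimulus.

    Frame indices are 0-based and local to the episode; the response window
    is the half-open interval [onset_frame, n_frames).
    """

    stimulus: StimulusClass
    n_frames: int
    baseline_frames: int
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if not (
            0 < self.baseline_frames <= self.onset_frame
            and self.onset_frame <= self.offset_frame < self.n_frames
        ):
            raise ValueError(
                "episode frame layout must satisfy "
                "0 < baseline_frames <= onset_frame <= offset_frame < n_frames; "
                f"got baseline={self.baseline_frames}, onset={self.onset_frame}, "
                f"offset={self.offset_frame}, n_frames={self.n_frames}"
            )


@dataclass(frozen=True)
class EpisodeSchedule:
    """Ordered stimulus episodes sharing one frame rate.

    ``episode_starts`` gives each episode's first frame index in the
    concatenated session; episodes are stored back-to-back (the pauses
    between epochs are boundary markers, not recorded frames).
    """

    episodes: tuple[Episode, ...]
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if not self.episodes:
            raise ValueError("schedule must contain at least one episode")

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def total_frames(self) -> int:
        return sum(ep.n_frames for ep in self.episodes)

    @property
    def episode_starts(self) -> tuple[int, ...]:
        starts, t = [], 0
        for ep in self.episodes:
            starts.append(t)
            t += ep.n_frames
        return tuple(starts)

    def episode_slice(self, i: int) -> slice:
        """Global frame slice of episode ``i`` in the concatenated session."""
        start = self.episode_starts[i]
        return slice(start, start + self.episodes[i].n_frames)

    def episodes_of_site(self, site: Site) -> list[int]:
        return [i for i, ep in enumerate(self.episodes) if ep.stimulus.site == site]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame_rate_hz": self.frame_rate_hz,
            "episodes": [
                {
                    "stimulus": ep.stimulus.name.value,
                    "intensity_label": ep.stimulus.intensity_label,
                    "n_frames": ep.n_frames,
                    "baseline_frames": ep.baseline_frames,
                    "onset_frame": ep.onset_frame,
                    "offset_frame": ep.offset_frame,
                }
                for ep in self.episodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpisodeSchedule":
        episodes = tuple(
            Episode(
                stimulus=StimulusClass(
                    Stimulus(e["stimulus"]), e.get("intensity_label", "")
                ),
                n_frames=int(e["n_frames"]),
                baseline_frames=int(e["baseline_frames"]),
                onset_frame=int(e["onset_frame"]),
                offset_frame=int(e["offset_frame"]),
            )
            for e in d["episodes"]
        )
        return cls(episodes=episodes, frame_rate_hz=float(d["frame_rate_hz"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "EpisodeSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


_DEFAULT_INTENSITY = {
    Stimulus.PUFF: "25 psi, 0.2/1/3/5 s",
    Stimulus.BALLOON_INFLATE: "100/150/200 mmHg",
}


def generate_schedule(
    frame_rate_hz: float = 5.0,
    episode_s: float = 40.0,
    baseline_s: float = 8.0,
    stimuli: tuple[Stimulus, ...] = DEFAULT_PROTOCOL,
) -> EpisodeSchedule:
    """Build the episode schedule for a stimulation session.

    Defaults reproduce the standard protocol: seven 40-s episodes at 5 Hz
    (200 frames each) with an 8-s (40-frame) baseline; the stimulus onset is
    placed at the first post-baseline frame and the response window runs to
    the end of the episode.

    Raises
    ------
    ValueError
        If any duration or the frame rate is non-positive.
    """
    if frame_rate_hz <= 0 or episode_s <= 0 or baseline_s <= 0:
        raise ValueError(
            "frame_rate_hz, episode_s and baseline_s must all be > 0; got "
            f"{frame_rate_hz}, {episode_s}, {baseline_s}"
        )
    n_frames = round(episode_s * frame_rate_hz)
    baseline_frames = round(baseline_s * frame_rate_hz)
    if not 0 < baseline_frames < n_frames:
        raise ValueError(
            f"baseline ({baseline_frames} frames) must be shorter than the "
            f"episode ({n_frames} frames)"
        )
    episodes = tuple(
        Episode(
            stimulus=StimulusClass(s, _DEFAULT_INTENSITY.get(s, "")),
            n_frames=n_frames,
            baseline_frames=baseline_frames,
            onset_frame=baseline_frames,
            offset_frame=n_frames - 1,
        )
        for s in stimuli
    )
    return EpisodeSchedule(episodes=episodes, frame_rate_hz=frame_rate_hz)
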