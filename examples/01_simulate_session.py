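"""Simulate a ground-truthed seven-episode imaging session.

Builds the standard stimulation schedule (7 x 40 s episodes at 5 Hz, 8 s
baselines), plants ~34 cells of known response class on a 256x256 field and
renders a noisy fluorescence movie.  Printed: the schedule geometry and the
planted class mix — the ground truth every later stage is scored against.
"""

from collections import Counter

from drgcal import simulate_session

cells, schedule, movie = simulate_session(seed=1)

print(f"schedule: {schedule.n_episodes} episodes, "
      f"{schedule.episodes[0].n_frames} frames each at "
      f"{schedule.frame_rate_hz:g} Hz, baseline "
      f"{schedule.episodes[0].baseline_frames} frames")
print(f"movie: {movie.data.shape} (frames x height x width), "
      f"min {movie.data.min():.1f}, max {movie.data.max():.1f}")
print("planted classes:", dict(Counter(c.planted_class.value for c in cells)))
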