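"""Generate a small synthetic accelerometer study and look at its files.

Two animals wear a neck-collar and an ear-tag accelerometer (25 Hz) for a
30-minute observation window while licking, eating, standing and lying
alternate. One signal CSV is written per animal x deployment and one
annotation CSV per animal, mimicking a video-annotated sensor deployment.
"""

import datetime as dt
from pathlib import Path

from bovilick.synthio import StudyConfig, sample_schedule, write_study

out_dir = Path("scratch/example_study")
config = StudyConfig(
    n_animals=2,
    n_days=1,
    seed=11,
    observation_window=(dt.time(10, 0), dt.time(10, 30)),
)

manifest = write_study(config, out_dir)
print(f"wrote {len(manifest)} files to {out_dir}:")
for path in manifest:
    print(f"  {path.name:32s} {path.stat().st_size / 1024:7.1f} kB")

log = sample_schedule(config, day=0, animal_id="a00")
print(f"\nschedule for animal a00 ({len(log)} events):")
for event in log.events[:5]:
    print(f"  {event.start.time()}  {event.behaviour:9s} {event.duration_s:6.1f} s")
print("  ...")
# Event durations tile the whole window; every behaviour recurs many times,
# so each contributes enough 10 s epochs for classifier training.
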