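"""Export GeoJSON performance maps for a scheduled cycling session.

Simulates a 10 min scheduled ride with a GPS track around a rectangular
course, then writes two overlays: the task map (intervals coloured by
riding task) and the cadence map (alternating segments annotated with
pedal-stroke counts and a rolling cadence average).
"""

import os

from tricadence import (
    SyntheticSessionSpec,
    balanced_schedule,
    cadence_series,
    default_profiles,
    detect_events,
    export_cadence_map,
    export_task_map,
    simulate_cycling_session,
    simulate_gps_track,
)

out_dir = "example_outputs"
os.makedirs(out_dir, exist_ok=True)

spec = SyntheticSessionSpec(
    "cycle", duration_s=600.0, task_schedule=balanced_schedule(10), seed=3
)
rec, truth = simulate_cycling_session(spec)
rec.gps = simulate_gps_track(599.9, speed_mps=8.33, jitter_m=0.5, seed=3)
rec.validate()

task_path = os.path.join(out_dir, "task_map.geojson")
segments = export_task_map(rec.gps, truth.label_track, task_path)
print(f"{task_path}: {len(segments)} task segments "
      f"(red = out-of-saddle, green = in-saddle, grey = coasting)")

events = detect_events(rec, default_profiles()["cycle"])
series = cadence_series(events, epoch_s=30.0, duration_s=rec.duration_s)
cad_path = os.path.join(out_dir, "cadence_map.geojson")
segments = export_cadence_map(rec.gps, series, interval_s=60.0,
                              rolling_window=3, path=cad_path)
print(f"{cad_path}: {len(segments)} cadence intervals, e.g. "
      f"{segments[0]['properties']['event_count']} pedal strokes in the first "
      f"minute (rolling {segments[0]['properties']['rolling_cadence_per_min']:.0f}/min)")
# drop either file onto any GeoJSON viewer to see where on the course each
# task or cadence change happened
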