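"""A full scripted monitor session: fever episodes + cough detection.

The face temperature cycles across the 38 C threshold twice while a cough
is played at t = 5 s; the monitor calibrates once, then watches both paths
and emits one packet per detection through a single ordered queue.
"""

from thermocough.audio import classifier, synth
from thermocough.monitor import (
    MonitorConfig,
    cough_in_ambient_stream,
    run_monitor,
    scripted_thermal_source,
)
from thermocough.thermal.sim import SensorModel

manifest = synth.build_dataset(300, seed=0)
model = classifier.build_model(classifier.ModelConfig(seed=0))
classifier.train_model(model, manifest, classifier.TrainConfig(epochs=6, seed=0))

face_temps = [37.0, 37.8, 38.4, 38.6, 38.1, 37.5, 37.0,
              37.3, 38.5, 38.2, 37.6, 37.0]
sensor = SensorModel(gain=0.97, offset=0.5, noise_sd=0.05, seed=0)
warmup, frames = scripted_thermal_source(face_temps, sensor)
stream = cough_in_ambient_stream(10.0, cough_times=[5.0], seed=1)

result = run_monitor(MonitorConfig(), warmup, frames, stream, model)
print(f"log entries: {len(result.event_log)}; packets: {len(result.packets)}")
for p in result.packets:
    extra = (f"temperature {p.temperature:.2f} C" if p.type == "thermal"
             else f"{len(p.audio)} base64 chars")
    print(f"  t={p.time:>3d}s  {p.type:8s} {extra}")
print("Two fever episodes (one packet per threshold crossing, re-armed "
      "after cooling 0.2 C below 38 C) and one debounced cough event.")
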