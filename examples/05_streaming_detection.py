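"""Sliding-window cough detection in a continuous audio stream.

Two coughs 0.3 s apart merge into one event (debouncing); coughs 3 s apart
stay separate.  Windows are 1 s with 50 % overlap so a cough cannot vanish
by straddling a window boundary.
"""

from thermocough.audio import classifier, synth
from thermocough.monitor import cough_in_ambient_stream

manifest = synth.build_dataset(300, seed=0)
model = classifier.build_model(classifier.ModelConfig(seed=0))
classifier.train_model(model, manifest, classifier.TrainConfig(epochs=6, seed=0))

for label, times in [("two coughs 0.3 s apart", [2.0, 2.3]),
                     ("two coughs 3 s apart", [2.0, 5.0])]:
    stream = cough_in_ambient_stream(10.0, cough_times=times, seed=4)
    events = classifier.classify_stream(stream, model)
    spans = ", ".join(f"{e.start:.1f}-{e.end:.1f}s (p={e.confidence:.2f})"
                      for e in events)
    print(f"{label}: {len(events)} event(s): {spans}")
print("Close repetitions debounce into one event; distant coughs are "
      "reported individually.")
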