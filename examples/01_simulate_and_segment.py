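"""Generate a synthetic 2-channel sEMG dataset and segment it into windows.

Each of the 6 grasp classes is band-limited noise in its own frequency
band with a class-specific contraction envelope; a 6-s trial at 500 Hz
yields 13 sliding windows of 2000 samples at an 80-sample hop.
"""

import semgrasp as sg

recordings, manifest = sg.generate_dataset(sg.SynthConfig(trials_per_class=2, seed=0))
print(f"{len(recordings)} trials, labels: {manifest.labels}")

rec = recordings[0]
print(f"first trial: subject={rec.subject_id} class={rec.class_label} "
      f"shape={rec.samples.shape} ({rec.duration_s:.0f} s at {rec.sample_rate_hz:.0f} Hz)")

windows = sg.segment(rec, size=2000, step=80)
print(f"{len(windows)} windows; starts {windows[0].start_index}..{windows[-1].start_index}")
# 13 windows per trial: floor((3000 - 2000) / 80) + 1, trailing samples dropped.
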