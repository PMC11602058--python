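"""Extract the four features (MAV, MDF, MNF, PeEn) from a decomposed window.

Every channel contributes (K + 1) x 4 features: the four statistics for
each mode (ascending centre frequency) and for the residual. With 2
channels and K=10 the vector has 88 entries — the feature space the
ReliefF ranking operates on.
"""

import semgrasp as sg

recordings, _ = sg.generate_dataset(sg.SynthConfig(trials_per_class=1, seed=1))
window = sg.segment(recordings[0], size=2000, step=80)[0]

mode_sets = sg.decompose_window(window, sg.VmdConfig(K=10))
fv = sg.extract_features(mode_sets, class_label=window.class_label)
print(f"feature vector length: {fv.values.size} (2 channels x 11 components x 4)")
for name, value in list(zip(fv.names, fv.values))[:8]:
    print(f"  {name:18s} = {value:8.3f}")
print("  ...")
# MAV is in signal units; MDF/MNF are in Hz; PeEn is in nats (<= ln 3! = 1.79).
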