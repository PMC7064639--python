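"""Simulate a block-design fNIRS session and look at its anatomy.

Two mental tasks (mental arithmetic vs idle), 30 trials each, 10-s task
periods with 15-17 s breaks, 9 channels at 12.5 Hz — the standard
prefrontal montage geometry.  Each trial evokes a double-gamma
hemodynamic response; cardiac, respiratory, Mayer-wave, drift and white
noise ride on top.
"""

import numpy as np

from nirsbag import SynthSessionConfig, generate_session

recording, events = generate_session(SynthSessionConfig(seed=42))

gaps = np.diff(events.onsets)
print(f"channels:        {recording.n_channels} "
      f"({recording.n_channels // 2} source-detector pairs x HbO/HbR)")
print(f"sampling rate:   {recording.sampling_rate} Hz")
print(f"duration:        {recording.duration / 60:.1f} min")
print(f"trials:          {len(events)} "
      f"({events.labels.count('MA')} MA / {events.labels.count('IS')} IS)")
print(f"inter-onset gap: {gaps.min():.1f}-{gaps.max():.1f} s "
      "(task 10 s + break 15-17 s)")
print(f"peak |ΔHbO|:     {np.abs(recording.data[:, 0]).max():.2f} µmol/L")
# The gap range shows the randomized break; the peak amplitude mixes the
# 0.15 µmol/L evoked response with physiological noise an order of
# magnitude larger — the classification problem the pipeline must solve.
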