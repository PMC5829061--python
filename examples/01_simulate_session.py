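"""Generate a synthetic EEG+NIRS session and inspect its structure.

A session holds two synchronized streams: 21-channel EEG (plus a vertical
EOG reference) at 200 Hz and 16-channel, 3-wavelength NIRS optical
densities at 13.3 Hz, with 90 task onsets (30 each of mental arithmetic
MA, motor imagery MI, idle state IS) spaced 26-28 s apart.
"""

import numpy as np

from hbci import SimulationConfig, simulate_session

cfg = SimulationConfig(seed=7)
eeg, nirs = simulate_session(cfg)

print(f"EEG : {eeg.n_channels} channels x {eeg.n_samples} samples "
      f"@ {eeg.rate:g} Hz ({eeg.duration / 60:.1f} min)")
print(f"NIRS: {nirs.n_channels} rows (16 channels x 3 wavelengths) "
      f"@ {nirs.rate:g} Hz")

labels = [e.class_label for e in eeg.events]
print(f"events: {len(labels)} trials -> "
      + ", ".join(f"{c}={labels.count(c)}" for c in ("MA", "MI", "IS")))

onsets = np.array([e.onset_sample for e in eeg.events]) / eeg.rate
print(f"onset spacing: {np.diff(onsets).min():.1f}-{np.diff(onsets).max():.1f} s "
      "(10 s task + 16-18 s break)")
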