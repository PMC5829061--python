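"""Condition raw streams into analysis-ready epochs.

EEG: band-pass 0.1-50 Hz, regress out the EOG reference, cut -5..25 s
epochs.  NIRS: convert optical densities to (HbR, HbO) via the modified
Beer-Lambert law, band-pass 0.01-0.09 Hz, epoch with a -1..0 s baseline.
"""

import numpy as np

from hbci import PipelineConfig, SimulationConfig, simulate_session
from hbci.pipeline import preprocess_eeg, preprocess_nirs

cfg = PipelineConfig()
eeg_rec, nirs_rec = simulate_session(SimulationConfig(seed=7))

eeg_epochs = preprocess_eeg(eeg_rec, cfg)
nirs_epochs = preprocess_nirs(nirs_rec, cfg)

print(f"EEG epochs : {eeg_epochs.data.shape}  (trials x channels x samples)")
print(f"NIRS epochs: {nirs_epochs.data.shape}  (trials x [16 ch x 2 chromophores] x samples)")
print(f"epoch time axis: {eeg_epochs.time_axis[0]:.2f} .. "
      f"{eeg_epochs.time_axis[-1]:.3f} s relative to task onset")

# baseline correction leaves the -1..0 s window at zero mean
mask = nirs_epochs.time_mask(-1.0, 0.0)
print(f"max |baseline mean| after correction: "
      f"{np.abs(nirs_epochs.data[:, :, mask].mean(axis=2)).max():.2e} mM*cm")
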