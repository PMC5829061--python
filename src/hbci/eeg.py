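"""EEG conditioning: downsampling, band-pass filtering, EOG removal, epoching.

The conditioning chain mirrors a standard motor-imagery/mental-arithmetic
protocol: resample to 200 Hz, band-pass 0.1-50 Hz (removes DC drift and
line noise), regress out the vertical-EOG reference, and cut -5..25 s
epochs around task onsets.

"Zero-phase" filters are 6th-order Butterworth designs applied
forward-backward (12th-order effective magnitude response, no group
delay).  The 0.1 Hz high-pass edge at 200 Hz is applied via second-order
sections; a direct-form filter of that order is numerically unstable at
such a low normalized frequency.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .config import FilterSpec
from .data import ContinuousRecording, EpochSet, rescale_events

__all__ = ["downsample", "bandpass", "remove_eog", "epoch"]


def downsample(rec: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Resample to ``target_rate`` with anti-alias filtering.

    Uses polyphase rational resampling (Kaiser-windowed FIR low-pass,
    stop-band attenuation well beyond 60 dB).  Event onsets are rescaled to
    the new rate and rounded to the nearest sample, ties toward zero.
    """
    if target_rate >= rec.rate:
        raise ValueError(
            f"target rate {target_rate} Hz must be below current {rec.rate} Hz"
        )
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # sharp anti-alias FIR: ~4 % of the target Nyquist as transition width,
    # > 60 dB stop-band, so tones just below the new Nyquist survive intact
    half_len = 20 * max(up, down)
    cutoff = min(1.0 / up, 1.0 / down)
    taps = signal.firwin(2 * half_len + 1, cutoff, window=("kaiser", 7.0))
    data = signal.resample_poly(rec.data, up, down, axis=1, window=taps)
    return ContinuousRecording(
        data=data,
        rate=target_rate,
        channels=list(rec.channels),
        events=rescale_events(rec.events, rec.rate, target_rate),
        unit=rec.unit,
    )


def bandpass(rec: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Butterworth band-pass; forward-backward when ``spec.zero_phase``.

    For ``low_hz > 0`` the output is DC-free.
    """
    from .nirs import _sos_bandpass

    data = _sos_bandpass(rec.data, rec.rate, spec)
    return ContinuousRecording(
        data=data, rate=rec.rate, channels=list(rec.channels),
        events=list(rec.events), unit=rec.unit,
    )


def _regress_out(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Least-squares removal of the EOG subspace from each EEG channel."""
    # solve eog.T @ beta = eeg.T in the least-squares sense
    beta, *_ = np.linalg.lstsq(eog.T, eeg.T, rcond=None)
    return eeg - beta.T @ eog


def remove_eog(
    rec: ContinuousRecording,
    eog_channel_names: Sequence[str] | None = None,
    method: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> ContinuousRecording:
    """Remove ocular-artifact contributions using EOG reference channel(s).

    The removal strategy is pluggable: ``method(eeg, eog) -> cleaned_eeg``
    operates on (channels x samples) arrays.  The default regresses each
    EEG channel on the EOG channel(s) and keeps the residual.  EOG channels
    are dropped from the output.
    """
    if eog_channel_names is None:
        eog_channel_names = [c.name for c in rec.channels if c.modality == "EOG"]
    names = set(eog_channel_names)
    if not names:
        raise ValueError(
            "no EOG channel found; skip the ocular-rejection stage instead"
        )
    missing = names - set(rec.channel_names())
    if missing:
        raise ValueError(f"EOG channel(s) not present: {sorted(missing)}")

    eog_rows = [i for i, c in enumerate(rec.channels) if c.name in names]
    keep_rows = [i for i, c in enumerate(rec.channels) if c.name not in names]
    eog = rec.data[eog_rows]
    eeg = rec.data[keep_rows]
    cleaned = (method or _regress_out)(eeg, eog)
    return ContinuousRecording(
        data=cleaned,
        rate=rec.rate,
        channels=[rec.channels[i] for i in keep_rows],
        events=list(rec.events),
        unit=rec.unit,
    )


def _window_samples(rate: float, start_s: float, end_s: float) -> tuple[int, int]:
    """First sample offset and sample count for a half-open window.

    Sample ``k`` covers ``[k/rate, (k+1)/rate)``; the window keeps samples
    whose start time falls in ``[start_s, end_s)``, i.e. ``floor`` of the
    window length in samples.
    """
    k_start = int(np.ceil(start_s * rate - 1e-9))
    n = int(np.floor((end_s - start_s) * rate + 1e-9))
    return k_start, n


def epoch(rec: ContinuousRecording, window: tuple[float, float]) -> EpochSet:
    """Cut one epoch per event over the half-open ``[start_s, end_s)`` window.

    Trials are ordered by onset; labels are copied from the events.  Raises
    (naming the trial) if any epoch would extend beyond the recording.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError(f"empty epoch window {window}")
    k_start, n = _window_samples(rec.rate, start_s, end_s)
    if n < 1:
        raise ValueError(f"epoch window {window} contains no samples at "
                         f"{rec.rate} Hz")
    if not rec.events:
        raise ValueError("recording has no events to epoch around")

    trials = np.empty((len(rec.events), rec.n_channels, n))
    labels = []
    for t, ev in enumerate(rec.events):
        lo = ev.onset_sample + k_start
        hi = lo + n
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"trial {t} ({ev.class_label} at sample {ev.onset_sample}): "
                f"window {window} s exceeds recording bounds"
            )
        trials[t] = rec.data[:, lo:hi]
        labels.append(ev.class_label)

    time_axis = (k_start + np.arange(n)) / rec.rate
    return EpochSet(
        data=trials,
        time_axis=time_axis,
        labels=np.array(labels),
        rate=rec.rate,
        channels=list(rec.channels),
    )
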