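"""Performance metrics: accuracy summaries, information transfer rate,
relative improvements, and event-related spectral perturbation maps.

The information transfer rate (ITR) of an N-class selection with accuracy
p and trial length tau seconds is the Wolpaw bit rate

    ITR = 60/tau * [log2 N + p log2 p + (1 - p) log2((1 - p)/(N - 1))]

in bits per minute, zero at chance (p = 1/N) and log2(N) bits per trial at
p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EpochSet
from .classify import CVResult

__all__ = [
    "ITRQuery",
    "itr",
    "percent_improvement",
    "accuracy_summary",
    "ERSPMap",
    "ersp",
]


@dataclass(frozen=True)
class ITRQuery:
    """Accuracy p in [0,1], class count N >= 2, trial length tau > 0 s."""

    p: float
    n_classes: int
    tau_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("accuracy p must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not self.tau_s > 0:
            raise ValueError("trial length must be positive")


def itr(p: float | ITRQuery, n_classes: int | None = None,
        tau_s: float | None = None) -> float:
    """Wolpaw information transfer rate in bits per minute.

    ``p log2 p`` is taken as 0 at p = 0, and the error term as 0 at p = 1,
    making the formula continuous on [0, 1].
    """
    q = p if isinstance(p, ITRQuery) else ITRQuery(p, n_classes, tau_s)
    bits = np.log2(q.n_classes)
    if q.p > 0:
        bits += q.p * np.log2(q.p)
    if q.p < 1:
        bits += (1 - q.p) * np.log2((1 - q.p) / (q.n_classes - 1))
    return 60.0 / q.tau_s * float(bits)


def percent_improvement(a: float, b: float) -> float:
    """Relative improvement of rate ``a`` over reference ``b``, in percent."""
    if b <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (a - b) / b


def accuracy_summary(cv: CVResult) -> dict[str, tuple[float, float]]:
    """Per-modality (mean, sd) accuracy in percent.

    The mean is over repetitions of the fold-pooled accuracy; the sd is
    across repetitions.  Invariant to fold and repetition order.
    """
    out = {}
    for modality in cv.confusion:
        acc = cv.accuracies(modality) * 100.0
        out[modality] = (float(acc.mean()), float(acc.std(ddof=1)) if len(acc) > 1 else 0.0)
    return out


@dataclass
class ERSPMap:
    """Time-frequency power change in dB relative to a pre-task baseline."""

    values_db: np.ndarray  # frequencies x times
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float]

    def band_mean(self, f_lo: float, f_hi: float, t_lo: float,
                  t_hi: float) -> float:
        """Mean dB over a frequency band and time window."""
        fm = (self.freqs >= f_lo) & (self.freqs < f_hi)
        tm = (self.times >= t_lo) & (self.times < t_hi)
        if not fm.any() or not tm.any():
            raise ValueError("requested band/window is outside the map")
        return float(self.values_db[np.ix_(fm, tm)].mean())


def ersp(
    epochs: EpochSet,
    baseline: tuple[float, float] = (-4.0, -3.0),
    channels: list[int] | str | None = None,
    window_s: float = 1.0,
    overlap: float = 0.9,
) -> ERSPMap:
    """Event-related spectral perturbation averaged over trials and a
    channel group.

    Short-time spectra (Hann window of ``window_s`` seconds, 90 % overlap)
    are averaged over trials and channels, divided per frequency by the
    mean power inside the ``baseline`` window (which must precede task
    onset), and expressed in dB: negative values mark event-related
    desynchronization, positive synchronization.

    ``channels`` may be a list of channel indices or a region name
    ("frontal"/"central"); default is all channels.
    """
    if baseline[0] >= baseline[1]:
        raise ValueError("empty baseline window")
    if baseline[1] > 0:
        raise ValueError("baseline window must precede task onset")
    if baseline[0] < epochs.time_axis[0] or baseline[1] > epochs.time_axis[-1]:
        raise ValueError("baseline window lies outside the epochs")

    if channels is None:
        rows = list(range(epochs.n_channels))
    elif isinstance(channels, str):
        rows = [i for i, c in enumerate(epochs.channels) if c.region == channels]
        if not rows:
            raise ValueError(f"no channels in region {channels!r}")
    else:
        rows = list(channels)

    nper = int(round(window_s * epochs.rate))
    nover = int(round(overlap * nper))
    x = epochs.data[:, rows, :]  # trials x channels x time
    freqs, times, sxx = signal.spectrogram(
        x, fs=epochs.rate, window="hann", nperseg=nper, noverlap=nover,
        detrend=False, mode="psd", axis=-1,
    )
    power = sxx.mean(axis=(0, 1))  # freqs x times
    times = times + epochs.time_axis[0]

    base_mask = (times >= baseline[0]) & (times < baseline[1])
    if not base_mask.any():
        raise ValueError("baseline window contains no spectrogram frames")
    base = power[:, base_mask].mean(axis=1, keepdims=True)
    values = 10.0 * np.log10(power / base)
    return ERSPMap(values_db=values, freqs=freqs, times=times,
                   baseline=baseline)
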