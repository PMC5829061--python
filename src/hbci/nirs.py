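"""NIRS conditioning: optical density to hemoglobin, band-pass, epoching.

The modified Beer-Lambert law (MBLL) maps optical-density changes at three
laser wavelengths (780, 805, 830 nm) to chromophore concentration changes
(reduced and oxidized hemoglobin) through a fixed 2x3 coefficient matrix::

    (dHbR)   ( 1.8545  -0.2394  -1.0947) (dOD780)
    (dHbO) = (-1.4887   0.5970   1.4847) (dOD805)   [mM*cm]
                                         (dOD830)

Unit pathlength is assumed (no differential pathlength factor), so outputs
are concentration change times pathlength, mM*cm.  Chromophore order is
fixed as (HbR, HbO) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import FilterSpec
from .data import ContinuousRecording, EpochSet, HemoglobinSeries

__all__ = [
    "MBLL_MATRIX",
    "NIRS_WAVELENGTHS",
    "HemoglobinConverter",
    "mbll_convert",
    "nirs_bandpass",
    "nirs_epoch_baseline",
]

#: MBLL coefficients, rows (HbR, HbO), columns (780, 805, 830 nm).
MBLL_MATRIX = np.array(
    [
        [1.8545, -0.2394, -1.0947],
        [-1.4887, 0.5970, 1.4847],
    ]
)

NIRS_WAVELENGTHS = (780.0, 805.0, 830.0)


@dataclass(frozen=True)
class HemoglobinConverter:
    """The MBLL coefficient matrix; replaceable for other wavelength sets."""

    matrix: np.ndarray = field(default_factory=lambda: MBLL_MATRIX.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError("conversion matrix must be 2x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("conversion matrix entries must be finite")
        object.__setattr__(self, "matrix", m)


def _group_od_channels(rec: ContinuousRecording) -> dict[tuple[int, int], dict[float, int]]:
    """Map (source, detector) -> {wavelength: row index} for OD channels."""
    groups: dict[tuple[int, int], dict[float, int]] = {}
    for i, ch in enumerate(rec.channels):
        if ch.modality != "NIRS":
            continue
        if ch.wavelength_nm is None:
            raise ValueError(f"OD channel {ch.name!r} lacks a wavelength")
        groups.setdefault((ch.source, ch.detector), {})[ch.wavelength_nm] = i
    return groups


def mbll_convert(
    od_rec: ContinuousRecording,
    conv: HemoglobinConverter | None = None,
) -> HemoglobinSeries:
    """Convert a 3-wavelength OD recording to (HbR, HbO) per channel.

    The conversion is linear and memoryless: for each source-detector pair
    and sample, ``(HbR, HbO) = C @ (OD780, OD805, OD830)``.

    Raises if any source-detector pair misses one of the three wavelengths.
    """
    conv = conv or HemoglobinConverter()
    if od_rec.unit != "OD":
        raise ValueError(f"expected an OD recording, got unit {od_rec.unit!r}")
    groups = _group_od_channels(od_rec)
    if not groups:
        raise ValueError("recording contains no NIRS channels")

    names, traces = [], []
    for (src, det), rows in sorted(groups.items()):
        missing = [w for w in NIRS_WAVELENGTHS if w not in rows]
        if missing:
            raise ValueError(
                f"channel S{src}-D{det} missing wavelength(s) {missing}"
            )
        od = od_rec.data[[rows[w] for w in NIRS_WAVELENGTHS]]  # 3 x n
        traces.append(conv.matrix @ od)  # 2 x n, (HbR, HbO)
        names.append(f"S{src}-D{det}")

    return HemoglobinSeries(
        data=np.stack(traces),
        rate=od_rec.rate,
        channel_names=names,
        events=list(od_rec.events),
    )


def _sos_bandpass(data: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Butterworth band-pass via second-order sections, along the last axis."""
    spec.validate_for_rate(rate)
    if spec.low_hz > 0:
        sos = signal.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
            fs=rate, output="sos",
        )
    else:
        sos = signal.butter(spec.order, spec.high_hz, btype="lowpass",
                            fs=rate, output="sos")
    if spec.zero_phase:
        # pad by ~2 periods of the low band edge: the filter's settling time
        # scales with 1/low_hz, and sub-0.1 Hz edges are transient-dominated
        edge = spec.low_hz if spec.low_hz > 0 else spec.high_hz
        padlen = min(
            data.shape[-1] - 1,
            max(3 * (2 * spec.order + 1), int(2 * rate / edge)),
        )
        return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)
    return signal.sosfilt(sos, data, axis=-1)


def nirs_bandpass(
    hb: HemoglobinSeries,
    spec: FilterSpec | None = None,
) -> HemoglobinSeries:
    """Band-pass each chromophore trace; default 0.01-0.09 Hz, 6th order,
    zero-phase, removing cardiac (~1.1 Hz), respiratory (~0.25 Hz) and
    Mayer-wave (~0.1 Hz) oscillations while keeping the task response."""
    spec = spec or FilterSpec(0.01, 0.09)
    flat = hb.data.reshape(-1, hb.n_samples)
    out = _sos_bandpass(flat, hb.rate, spec).reshape(hb.data.shape)
    return HemoglobinSeries(
        data=out, rate=hb.rate, channel_names=list(hb.channel_names),
        events=list(hb.events),
    )


def nirs_epoch_baseline(
    hb: HemoglobinSeries,
    window: tuple[float, float] = (-5.0, 25.0),
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> EpochSet:
    """Epoch hemoglobin traces and subtract the per-trial baseline mean.

    The baseline is the temporal mean over ``baseline`` (default -1..0 s,
    just before task onset), subtracted per trial, per channel and per
    chromophore.  Returns an EpochSet whose channel axis is channel-major
    with chromophore inner: ``[ch0:HbR, ch0:HbO, ch1:HbR, ...]``.
    """
    from .eeg import epoch  # shared epoching conventions

    if not (window[0] <= baseline[0] < baseline[1] <= window[1]):
        raise ValueError(
            f"baseline window {baseline} must lie inside epoch window {window}"
        )
    epochs = epoch(hb.as_recording(), window)
    mask = epochs.time_mask(*baseline)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    epochs.data -= epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs
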