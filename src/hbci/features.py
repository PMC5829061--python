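"""Filter-bank CSP features for EEG and temporal-mean features for NIRS.

Common spatial patterns (CSP) finds spatial filters w maximizing the
variance ratio ``w' C_A w / w' (C_A + C_B) w`` between two task classes,
via the generalized eigenproblem ``C_A w = lambda (C_A + C_B) w``.  The
eigenvalue lambda in [0, 1] is the class-A variance fraction of that
component and serves as its selection score: components with extreme
scores (near 1 or near 0) are the most discriminative, so the first three
and last three components by score are kept.  Applied independently per
band of a theta/alpha/beta filter bank this yields 6 components x 3 bands
= 18 log-variance features per trial and binary problem.

NIRS features are per-channel temporal means of baseline-corrected HbR and
HbO in the 5-10 s and 10-15 s windows (the hemodynamic response is slow,
peaking several seconds after task onset): 16 channels x 2 chromophores x
2 windows = 64 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .config import FilterSpec
from .data import EpochSet

__all__ = [
    "FilterBankSpec",
    "SpatialFilterSet",
    "FeatureMatrix",
    "csp_fit",
    "csp_select",
    "fbcsp_features",
    "nirs_mean_features",
]

#: relative ridge added to the composite covariance diagonal
_COV_EPS = 1e-10


def default_filter_bank() -> "FilterBankSpec":
    return FilterBankSpec()


@dataclass(frozen=True)
class FilterBankSpec:
    """Band-pass bank; default theta 4-8, alpha 8-13, beta 13-30 Hz."""

    bands: tuple[FilterSpec, ...] = (
        FilterSpec(4, 8),
        FilterSpec(8, 13),
        FilterSpec(13, 30),
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank must contain at least one band")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class SpatialFilterSet:
    """CSP projection for one band and one binary problem.

    ``filters`` has one column per component; ``scores`` holds the class-A
    variance fraction of each component, sorted descending.  Columns
    jointly diagonalize the two class covariances and whiten their sum.
    """

    filters: np.ndarray  # channels x components
    scores: np.ndarray  # descending, in [0, 1]
    band: str = ""
    problem: str = ""

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.filters.shape[1] != len(self.scores):
            raise ValueError("one score per component required")
        if self.filters.shape[1] > self.filters.shape[0]:
            raise ValueError("component count cannot exceed channel count")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]


@dataclass
class FeatureMatrix:
    """Trials x features matrix with labels and provenance."""

    data: np.ndarray
    labels: np.ndarray
    modality: str
    problem: str = ""
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature matrix contains non-finite entries")


def task_covariances(
    epochs: EpochSet,
    task_window: tuple[float, float] = (0.0, 10.0),
    normalize: bool = True,
) -> np.ndarray:
    """Per-trial spatial covariance over the task window.

    With ``normalize`` each covariance is divided by its trace (standard
    CSP practice; makes spatial patterns robust to per-trial amplitude
    scale).  Raw (unnormalized) covariances are what log-variance features
    are computed from.
    """
    mask = epochs.time_mask(*task_window)
    if not mask.any():
        raise ValueError(f"task window {task_window} contains no samples")
    X = epochs.data[:, :, mask]
    Xc = X - X.mean(axis=2, keepdims=True)
    covs = np.einsum("tcs,tds->tcd", Xc, Xc) / X.shape[2]
    if normalize:
        traces = np.trace(covs, axis1=1, axis2=2)
        covs = covs / traces[:, None, None]
    return covs


def csp_fit_covariances(
    mean_cov_a: np.ndarray,
    mean_cov_b: np.ndarray,
    band: str = "",
    problem: str = "",
) -> SpatialFilterSet:
    """CSP from the two mean class covariances (core solver)."""
    composite = mean_cov_a + mean_cov_b
    ridge = _COV_EPS * np.mean(np.diag(composite))
    composite = composite + ridge * np.eye(composite.shape[0])
    try:
        scores, W = linalg.eigh(mean_cov_a, composite)
    except linalg.LinAlgError as err:
        raise ValueError(
            "rank-deficient composite covariance; regularize the input "
            "(e.g. drop linearly dependent channels) before CSP"
        ) from err
    order = np.argsort(scores)[::-1]
    scores, W = scores[order], W[:, order]
    # deterministic sign: largest-magnitude coefficient positive
    flips = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    W = W * np.where(flips == 0, 1.0, flips)
    return SpatialFilterSet(
        filters=W, scores=np.clip(scores, 0.0, 1.0), band=band, problem=problem
    )


def csp_fit(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    task_window: tuple[float, float] = (0.0, 10.0),
    band: str = "",
    problem: str = "",
) -> SpatialFilterSet:
    """Fit CSP between two classes of (already band-filtered) epochs.

    Per-trial covariances over the task window are trace-normalized and
    averaged per class; the generalized eigenproblem of the class-A mean
    against the composite yields filters whitening the composite
    (``W' (C_A + C_B) W = I``) with class-A variance fractions as scores.
    """
    for ep, nm in ((epochs_a, "A"), (epochs_b, "B")):
        if ep.n_trials < 2:
            raise ValueError(f"class {nm} needs at least 2 trials for CSP")
    if epochs_a.n_channels != epochs_b.n_channels:
        raise ValueError("both classes must share the channel set")
    ca = task_covariances(epochs_a, task_window).mean(axis=0)
    cb = task_covariances(epochs_b, task_window).mean(axis=0)
    return csp_fit_covariances(ca, cb, band=band, problem=problem)


def csp_select(filters: SpatialFilterSet, n_first: int = 3,
               n_last: int = 3) -> SpatialFilterSet:
    """Keep the ``n_first`` highest- and ``n_last`` lowest-scoring components."""
    if n_first < 0 or n_last < 0 or n_first + n_last < 1:
        raise ValueError("must keep at least one component")
    total = filters.n_components
    if n_first + n_last > total:
        raise ValueError(
            f"requested {n_first}+{n_last} components but only {total} available"
        )
    idx = list(range(n_first)) + list(range(total - n_last, total))
    return SpatialFilterSet(
        filters=filters.filters[:, idx],
        scores=filters.scores[idx],
        band=filters.band,
        problem=filters.problem,
    )


def bandpass_epochs(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase band-pass along the time axis of every trial."""
    from .nirs import _sos_bandpass

    data = _sos_bandpass(epochs.data, epochs.rate, spec)
    return EpochSet(
        data=data, time_axis=epochs.time_axis, labels=epochs.labels,
        rate=epochs.rate, channels=epochs.channels,
    )


def logvar_features(covs_raw: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Log-variance of each CSP component from raw per-trial covariances."""
    var = np.einsum("ck,tcd,dk->tk", W, covs_raw, W)
    if np.any(var <= 0):
        raise ValueError("zero variance in a CSP component (degenerate signal)")
    return np.log(var)


def fbcsp_features(
    epochs: EpochSet,
    bank: FilterBankSpec,
    filters_per_band: list[SpatialFilterSet],
    task_window: tuple[float, float] = (0.0, 10.0),
    problem: str = "",
) -> FeatureMatrix:
    """Project each band-filtered trial onto its CSP components and take
    the log of the task-window variance; concatenate across bands.

    The spatial filters must come from a disjoint training set — the
    cross-validation driver enforces that contract.
    """
    if len(filters_per_band) != bank.n_bands:
        raise ValueError("one SpatialFilterSet per bank band required")
    blocks, names = [], []
    for spec, flt in zip(bank.bands, filters_per_band):
        band_ep = bandpass_epochs(epochs, spec)
        covs = task_covariances(band_ep, task_window, normalize=False)
        blocks.append(logvar_features(covs, flt.filters))
        names += [
            f"{spec.low_hz:g}-{spec.high_hz:g}Hz_csp{j}"
            for j in range(flt.n_components)
        ]
    return FeatureMatrix(
        data=np.hstack(blocks), labels=epochs.labels, modality="eeg",
        problem=problem, feature_names=names,
    )


def nirs_mean_features(
    epochs: EpochSet,
    windows: tuple[tuple[float, float], ...] = ((5.0, 10.0), (10.0, 15.0)),
    problem: str = "",
) -> FeatureMatrix:
    """Temporal-mean features of baseline-corrected hemoglobin epochs.

    Expects the channel axis ordered channel-major with chromophore inner
    (as produced by ``nirs_epoch_baseline``); features are ordered
    channel-major, then chromophore, then window.
    """
    cols, names = [], []
    for row, ch in enumerate(epochs.channels):
        for w, (lo, hi) in enumerate(windows):
            mask = epochs.time_mask(lo, hi)
            if not mask.any():
                raise ValueError(
                    f"window [{lo}, {hi}) is empty after discretization at "
                    f"{epochs.rate} Hz"
                )
            cols.append(epochs.data[:, row, mask].mean(axis=1))
            names.append(f"{ch.name}_{lo:g}-{hi:g}s")
    return FeatureMatrix(
        data=np.column_stack(cols), labels=epochs.labels, modality="nirs",
        problem=problem, feature_names=names,
    )
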