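"""End-to-end orchestration: simulate/load -> preprocess -> evaluate -> report.

``run_pipeline`` executes the full decoding chain on a session (synthetic
by default) and returns a plain, JSON-serializable results dictionary
stamped with the configuration hash.  Identical configurations produce
byte-identical results JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import eeg as eeg_mod
from . import nirs as nirs_mod
from .classify import CVResult, crossvalidate
from .config import PipelineConfig
from .data import ContinuousRecording, EpochSet, read_session
from .metrics import accuracy_summary
from .simulate import SimulationConfig, simulate_session

__all__ = [
    "preprocess_eeg",
    "preprocess_nirs",
    "run_pipeline",
]


def preprocess_eeg(rec: ContinuousRecording, cfg: PipelineConfig) -> EpochSet:
    """Condition a raw EEG recording into broadband epochs.

    Order: downsample (if above the target rate) -> band-pass -> ocular
    rejection (if an EOG channel is present and enabled) -> epoch.
    """
    stage = "eeg downsample"
    try:
        if rec.rate > cfg.eeg_rate:
            rec = eeg_mod.downsample(rec, cfg.eeg_rate)
        stage = "eeg bandpass"
        rec = eeg_mod.bandpass(rec, cfg.eeg_band)
        if cfg.remove_eog and any(c.modality == "EOG" for c in rec.channels):
            stage = "eeg ocular rejection"
            rec = eeg_mod.remove_eog(rec)
        stage = "eeg epoching"
        return eeg_mod.epoch(rec, cfg.epoch_window)
    except Exception as err:
        raise RuntimeError(f"{stage} failed: {err}") from err


def preprocess_nirs(rec: ContinuousRecording, cfg: PipelineConfig) -> EpochSet:
    """Condition a raw OD recording: MBLL -> band-pass -> epoch + baseline."""
    stage = "nirs MBLL conversion"
    try:
        hb = nirs_mod.mbll_convert(rec)
        stage = "nirs bandpass"
        hb = nirs_mod.nirs_bandpass(hb, cfg.nirs_band)
        stage = "nirs epoching/baseline"
        return nirs_mod.nirs_epoch_baseline(
            hb, cfg.epoch_window, cfg.nirs_baseline
        )
    except Exception as err:
        raise RuntimeError(f"{stage} failed: {err}") from err


def run_pipeline(
    cfg: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    session_path: str | Path | None = None,
) -> dict:
    """Full chain on a simulated (default) or stored session.

    Returns a dictionary with per-modality accuracies (percent, mean and
    sd over repetitions), all confusion matrices, and the configuration
    hash for provenance.
    """
    cfg = cfg or PipelineConfig()
    if session_path is not None:
        eeg_rec, nirs_rec = read_session(session_path)
    else:
        sim = sim_config or SimulationConfig(seed=cfg.seed)
        eeg_rec, nirs_rec = simulate_session(sim)

    eeg_epochs = preprocess_eeg(eeg_rec, cfg)
    nirs_epochs = preprocess_nirs(nirs_rec, cfg)
    cv = crossvalidate(eeg_epochs, nirs_epochs, cfg)
    return build_results(cv, cfg)


def build_results(cv: CVResult, cfg: PipelineConfig) -> dict:
    summary = accuracy_summary(cv)
    return {
        "config_hash": cfg.config_hash(),
        "folds": cfg.folds,
        "repetitions": cfg.repetitions,
        "accuracy_percent": {
            m: {"mean": round(mean, 6), "sd": round(sd, 6)}
            for m, (mean, sd) in sorted(summary.items())
        },
        "confusion_matrices": {
            m: cv.confusion[m].astype(int).tolist() for m in sorted(cv.confusion)
        },
        "class_order": list(cv.class_order),
    }


def results_to_json(results: dict) -> str:
    return json.dumps(results, sort_keys=True, indent=2)
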