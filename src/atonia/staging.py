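"""Semi-automatic vigilance staging of 4-s epochs.

The classifier follows the two-step logic used for rodent polysomnography:
first the EMG decides between WAKE and sleep — an epoch with neck-muscle
activity above threshold is WAKE per se — then the EEG separates NREMS from
REMS in the spectral domain via the θ/δ power ratio (REMS is θ-dominant,
NREMS δ-dominant). Thresholds adapt per recording: the wake threshold is a
multiple of the median per-epoch EMG RMS, which absorbs inter-animal gain
differences, and the θ/δ cut is dimensionless.

A state change must persist for at least three epochs (12 s); shorter
excursions do not change the prevailing state and are kept only as
micro-arousal (short WAKE inside sleep) or transient annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_formats, spectral
from .core import (
    ARTIFACT,
    MICRO_AROUSAL,
    NREMS,
    REM_A,
    REMS,
    TRANSIENT,
    WAKE,
    Hypnogram,
    Recording,
)
from .errors import IntegrityError

FEATURE_COLUMNS = [
    "emg_rms",
    "delta_power",
    "theta_power",
    "theta_delta_ratio",
    "total_power",
    "amplitude_range",
    "artifact",
]


@dataclass
class StagingThresholds:
    """Per-recording decision thresholds (µV / dimensionless)."""

    emg_wake_threshold: float
    theta_delta_rems_threshold: float = 1.5
    artifact_amplitude: float = 750.0

    def __post_init__(self) -> None:
        if min(
            self.emg_wake_threshold,
            self.theta_delta_rems_threshold,
            self.artifact_amplitude,
        ) <= 0:
            raise IntegrityError("staging thresholds must be positive")


@dataclass
class StagingConfig:
    """Config keys for the staging step (see also the run-level YAML)."""

    emg_threshold_factor: float = 2.5
    emg_threshold_percentile: float = 25.0
    theta_delta_threshold: float = 1.5
    min_bout_epochs: int = 3
    artifact_amplitude_uV: float = 750.0
    epoch_len: float = 4.0
    eeg_channel: int = 0
    relative_power: bool = False  # normalize band powers by total power
    delta_band: tuple[float, float] = (0.5, 5.0)
    theta_band: tuple[float, float] = (5.0, 9.0)


@dataclass
class EpochSeries:
    """Raw-rate signals cut into non-overlapping epochs."""

    eeg: np.ndarray  # (n_channels, n_epochs, samples_per_epoch)
    emg: np.ndarray  # (n_epochs, samples_per_epoch)
    fs: float
    epoch_len: float

    @property
    def n_epochs(self) -> int:
        return self.emg.shape[0]


def segment(x: np.ndarray, fs: float, epoch_len: float = 4.0) -> np.ndarray:
    """Cut a trace into ``floor(n / (fs*epoch_len))`` epochs, dropping the
    trailing remainder."""
    spe = fs * epoch_len
    if abs(spe - round(spe)) > 1e-9:
        raise IntegrityError(
            f"fs*epoch_len = {spe} is not an integer sample count"
        )
    spe = int(round(spe))
    x = np.asarray(x, dtype=float)
    n_epochs = x.shape[-1] // spe
    return x[..., : n_epochs * spe].reshape(*x.shape[:-1], n_epochs, spe)


def segment_epochs(rec: Recording, epoch_len: float = 4.0) -> EpochSeries:
    """Segment a recording into 4-s epochs at its native sampling rate."""
    eeg = segment(rec.eeg, rec.fs, epoch_len)
    emg = segment(rec.emg, rec.fs, epoch_len)
    if emg.shape[0] == 0:
        warnings.warn("recording shorter than one epoch: empty epoch series")
    return EpochSeries(eeg=eeg, emg=emg, fs=rec.fs, epoch_len=epoch_len)


def emg_activity_score(emg_epochs: np.ndarray) -> np.ndarray | float:
    """RMS of the mean-subtracted epoch(s) — the per-epoch muscle-tone score."""
    x = np.asarray(emg_epochs, dtype=float)
    if x.size == 0:
        raise IntegrityError("empty EMG epoch")
    centered = x - x.mean(axis=-1, keepdims=True)
    rms = np.sqrt(np.mean(centered**2, axis=-1))
    return float(rms) if np.ndim(rms) == 0 else rms


def eeg_epoch_features(
    eeg_epochs: np.ndarray,
    fs: float = 125.0,
    delta_band: tuple[float, float] = (0.5, 5.0),
    theta_band: tuple[float, float] = (5.0, 9.0),
    relative_power: bool = False,
) -> pd.DataFrame:
    """Spectral/temporal features of 125 Hz EEG epochs (500 samples each).

    Epochs containing NaN samples get ``artifact=True`` and NaN features.
    The θ/δ ratio is +inf where δ power is zero and θ power is not.
    """
    eeg_epochs = np.atleast_2d(np.asarray(eeg_epochs, dtype=float))
    nan_rows = ~np.isfinite(eeg_epochs).all(axis=-1)
    clean = np.where(nan_rows[:, None], 0.0, eeg_epochs)
    freqs, psds = spectral.psd_per_epoch(clean, fs)
    delta = spectral.band_power((freqs, psds), delta_band)
    theta = spectral.band_power((freqs, psds), theta_band)
    total = spectral.band_power((freqs, psds), (freqs[0], freqs[-1]))
    if relative_power:
        safe_total = np.where(total > 0, total, 1.0)
        delta = delta / safe_total
        theta = theta / safe_total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.where(delta > 0, delta, 1.0), np.inf)
        ratio = np.where((delta == 0) & (theta == 0), 0.0, ratio)
    amp_range = clean.max(axis=-1) - clean.min(axis=-1)
    df = pd.DataFrame(
        {
            "delta_power": delta,
            "theta_power": theta,
            "theta_delta_ratio": ratio,
            "total_power": total,
            "amplitude_range": amp_range,
            "artifact": nan_rows,
        }
    )
    df.loc[nan_rows, ["delta_power", "theta_power", "theta_delta_ratio",
                      "total_power", "amplitude_range"]] = np.nan
    return df


def compute_features(rec: Recording, cfg: StagingConfig | None = None) -> pd.DataFrame:
    """Full per-epoch feature table: EMG RMS at the native rate plus EEG
    spectral/temporal features at the 125 Hz analysis rate."""
    cfg = cfg or StagingConfig()
    series = segment_epochs(rec, cfg.epoch_len)
    emg_rms = emg_activity_score(series.emg) if series.n_epochs else np.empty(0)
    eeg125 = io_formats.downsample_to_analysis_rate(
        rec.eeg[cfg.eeg_channel], rec.fs
    )
    eeg_epochs = segment(eeg125, io_formats.ANALYSIS_FS, cfg.epoch_len)
    n = min(len(emg_rms), eeg_epochs.shape[0])
    df = eeg_epoch_features(
        eeg_epochs[:n],
        io_formats.ANALYSIS_FS,
        cfg.delta_band,
        cfg.theta_band,
        cfg.relative_power,
    )
    df.insert(0, "emg_rms", np.asarray(emg_rms)[:n])
    return df


def calibrate_thresholds(
    features: pd.DataFrame, cfg: StagingConfig | None = None
) -> StagingThresholds:
    """Adaptive per-recording thresholds.

    The wake EMG cut is ``factor × percentile(emg_rms)``. The reference
    percentile defaults to the 25th: sleep occupies well over a quarter of
    any session, so that quantile always sits in the low-tone (sleep)
    cluster, whereas the median flips into the WAKE cluster for animals that
    are awake more than half the time and would push the threshold above
    every epoch.
    """
    cfg = cfg or StagingConfig()
    ref = float(
        np.nanpercentile(features["emg_rms"].to_numpy(), cfg.emg_threshold_percentile)
    )
    if ref <= 0:
        ref = 1e-6
    return StagingThresholds(
        emg_wake_threshold=cfg.emg_threshold_factor * ref,
        theta_delta_rems_threshold=cfg.theta_delta_threshold,
        artifact_amplitude=cfg.artifact_amplitude_uV,
    )


def classify_epochs(
    features: pd.DataFrame, th: StagingThresholds, epoch_len: float = 4.0
) -> Hypnogram:
    """EMG-first, EEG-second epoch classification.

    WAKE if the EMG RMS exceeds the wake threshold; otherwise REMS when the
    θ/δ ratio exceeds the REMS threshold, else NREMS. Epochs whose amplitude
    range exceeds the artifact limit (or with NaN features) are flagged
    ARTIFACT and their state imputed from the nearest scored neighbour.
    """
    emg = features["emg_rms"].to_numpy(dtype=float)
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)
    amp = features["amplitude_range"].to_numpy(dtype=float)
    nan_artifact = features["artifact"].to_numpy(dtype=bool)
    n = len(features)
    artifact = nan_artifact | (np.nan_to_num(amp) > th.artifact_amplitude)
    states = np.where(
        emg > th.emg_wake_threshold,
        WAKE,
        np.where(ratio > th.theta_delta_rems_threshold, REMS, NREMS),
    ).astype("<U5")
    # impute artifact epochs from the nearest preceding scored epoch
    # (falling back to the next one at the start of the session)
    if artifact.any():
        good = np.flatnonzero(~artifact)
        if good.size == 0:
            states[:] = NREMS
        else:
            idx = np.searchsorted(good, np.arange(n), side="right") - 1
            nearest = good[np.clip(idx, 0, good.size - 1)]
            states = states[nearest]
    return Hypnogram(
        states=states,
        flags={ARTIFACT: artifact},
        epoch_len=epoch_len,
    )


def enforce_min_bout(h: Hypnogram, min_epochs: int = 3) -> Hypnogram:
    """Suppress state changes shorter than ``min_epochs`` (default 3 = 12 s).

    A run shorter than the minimum does not change the prevailing state: its
    epochs are relabeled to the preceding accepted state and annotated as a
    MICRO_AROUSAL (short WAKE inside sleep) or TRANSIENT otherwise. The first
    run of the session is exempt (there is no preceding state). Idempotent.
    """
    out = h.copy()
    runs = h.runs()
    if not runs:
        return out
    accepted = runs[0].state
    for run in runs[1:]:
        if run.length >= min_epochs:
            accepted = run.state
            continue
        if run.state == accepted:
            continue  # a continuation interrupted by an earlier short run
        sl = slice(run.start, run.start + run.length)
        out.states[sl] = accepted
        if run.state == WAKE and accepted in (NREMS, REMS):
            out.flags[MICRO_AROUSAL][sl] = True
        else:
            out.flags[TRANSIENT][sl] = True
    # relabeling away from REMS must drop any REM-A annotation
    out.flags[REM_A] &= out.states == REMS
    return out


def stage_recording(
    rec: Recording, cfg: StagingConfig | None = None
) -> tuple[Hypnogram, pd.DataFrame, StagingThresholds]:
    """Stage a recording end to end.

    Returns the min-bout-enforced hypnogram, the per-epoch feature table and
    the calibrated thresholds. Deterministic: the same recording and config
    always produce the same hypnogram.
    """
    cfg = cfg or StagingConfig()
    features = compute_features(rec, cfg)
    th = calibrate_thresholds(features, cfg)
    raw = classify_epochs(features, th, cfg.epoch_len)
    return enforce_min_bout(raw, cfg.min_bout_epochs), features, th


def apply_override(h: Hypnogram, override: pd.DataFrame) -> Hypnogram:
    """Apply a manual-rescoring override table (columns ``epoch``, ``state``),
    the file-based stand-in for epoch-level review by a human scorer."""
    out = h.copy()
    for _, row in override.iterrows():
        out.states[int(row["epoch"])] = row["state"]
    out.flags[REM_A] &= out.states == REMS
    return out
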