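"""REM sleep without atonia (REM-A) detection and reporting.

Healthy REMS comes with near-complete loss of neck-muscle tone; REM-A —
the cardinal polysomnographic sign of REM-sleep behavior disorder — is one
or more REMS epochs with concurrent EMG activity. Two detection routes are
implemented:

1. REMS epochs whose per-epoch EMG RMS exceeds an atonia threshold are
   flagged REM_A directly (state stays REMS).
2. Short WAKE runs embedded in REMS are revisited: EMG-first staging labels
   any muscular epoch WAKE per se, so genuine REM-A with strong bursts lands
   in WAKE. A WAKE run is rescored to REMS+REM_A only when it is flanked on
   both sides by at least three consecutive atonic REMS epochs and every
   epoch in the run has REMS-like (θ-dominant) EEG — the automated stand-in
   for requiring an EEG unmistakably different from a WAKE EEG.

The atonia threshold is anchored on the atonic floor (a low percentile of
the REMS EMG distribution, default the 5th, times a safety factor) rather
than a high percentile, so it stays valid even when a large fraction of REMS
carries muscle activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MICRO_AROUSAL, REM_A, REMS, WAKE, Hypnogram
from .errors import UndefinedResultError


@dataclass
class RemaConfig:
    """Config keys for REM-A detection."""

    percentile: float = 5.0
    factor: float = 2.5
    margin: float = 0.0
    floor: float = 1.0  # µV; also the fallback when REMS is too scarce
    absolute_threshold: float | None = None
    min_flank_epochs: int = 3
    max_rescore_run: int = 3
    theta_delta_threshold: float = 1.5
    strict_eeg: bool = False  # additionally require REMS-like total power
    min_rems_epochs: int = 10


@dataclass
class RemaResult:
    """REM-A summary for one animal."""

    rema_epochs: int
    total_rems_epochs: int
    proportion: float  # percent of total REMS
    episodes: list[tuple[int, int]]  # (start_epoch, length) of flagged runs


def atonia_threshold(
    h: Hypnogram,
    emg_rms: np.ndarray,
    percentile: float = 5.0,
    factor: float = 2.5,
    margin: float = 0.0,
    floor: float = 1.0,
    min_rems_epochs: int = 10,
) -> float:
    """EMG RMS threshold (µV) separating atonic REMS from REM-A.

    ``factor × percentile(REMS EMG RMS) + margin``, never below ``floor``.
    With fewer than ``min_rems_epochs`` REMS epochs the threshold cannot be
    calibrated and the floor is returned. Monotone in ``percentile``.
    """
    emg_rms = np.asarray(emg_rms, dtype=float)
    rems_emg = emg_rms[: h.n_epochs][h.states[: len(emg_rms)] == REMS]
    if rems_emg.size < min_rems_epochs:
        return float(floor)
    return float(max(floor, factor * np.percentile(rems_emg, percentile) + margin))


def detect_rema_in_rems(
    h: Hypnogram, emg_rms: np.ndarray, threshold: float
) -> Hypnogram:
    """Flag every REMS epoch whose EMG RMS exceeds ``threshold`` as REM_A."""
    out = h.copy()
    emg = np.asarray(emg_rms, dtype=float)[: h.n_epochs]
    out.flags[REM_A] |= (out.states[: len(emg)] == REMS) & (emg > threshold)
    return out


def rescore_flanked_wake(
    h: Hypnogram,
    emg_rms: np.ndarray,
    features: pd.DataFrame,
    threshold: float,
    theta_delta_threshold: float = 1.5,
    min_flank_epochs: int = 3,
    max_run: int = 3,
    strict_eeg: bool = False,
) -> Hypnogram:
    """Rescore WAKE runs embedded in atonic REMS as REMS with REM-A.

    A WAKE run of at most ``max_run`` epochs is rescored iff (a) the
    ``min_flank_epochs`` epochs on each side are all REMS with EMG at or
    below the atonia threshold, and (b) every epoch in the run has a θ/δ
    ratio above the REMS threshold (with ``strict_eeg``, additionally a
    total power within the range spanned by the REMS epochs of the session).
    Longer WAKE runs are treated as genuine awakenings.
    """
    out = h.copy()
    emg = np.asarray(emg_rms, dtype=float)[: h.n_epochs]
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)[: h.n_epochs]
    atonic_rems = (h.states == REMS) & (emg <= threshold)
    if strict_eeg:
        total = features["total_power"].to_numpy(dtype=float)[: h.n_epochs]
        rems_total = total[h.states == REMS]
        power_ok = (
            (total >= rems_total.min()) & (total <= rems_total.max())
            if rems_total.size
            else np.zeros(h.n_epochs, dtype=bool)
        )
    for run in h.runs():
        if run.state != WAKE or run.length > max_run:
            continue
        lo, hi = run.start, run.start + run.length
        if lo < min_flank_epochs or hi + min_flank_epochs > h.n_epochs:
            continue
        if not atonic_rems[lo - min_flank_epochs : lo].all():
            continue
        if not atonic_rems[hi : hi + min_flank_epochs].all():
            continue
        eeg_ok = (ratio[lo:hi] > theta_delta_threshold).all()
        if strict_eeg:
            eeg_ok = eeg_ok and power_ok[lo:hi].all()
        if not eeg_ok:
            continue
        out.states[lo:hi] = REMS
        out.flags[REM_A][lo:hi] = True
        out.flags[MICRO_AROUSAL][lo:hi] = False  # no longer an arousal
    return out


def rema_summary(h: Hypnogram) -> RemaResult:
    """Counts, percent of total REMS, and the list of REM-A episodes.

    A hypnogram without any REMS has no defined REM-A proportion ("no REMS"
    is not 0%); that raises :class:`UndefinedResultError`.
    """
    total_rems = int(np.sum(h.states == REMS))
    if total_rems == 0:
        raise UndefinedResultError("hypnogram contains no REMS epochs")
    flags = h.flags[REM_A]
    rema_epochs = int(flags.sum())
    episodes = []
    in_ep = False
    for i, f in enumerate(flags):
        if f and not in_ep:
            start, in_ep = i, True
        elif not f and in_ep:
            episodes.append((start, i - start))
            in_ep = False
    if in_ep:
        episodes.append((start, len(flags) - start))
    return RemaResult(
        rema_epochs=rema_epochs,
        total_rems_epochs=total_rems,
        proportion=100.0 * rema_epochs / total_rems,
        episodes=episodes,
    )


def analyze_rema(
    h: Hypnogram,
    emg_rms: np.ndarray,
    features: pd.DataFrame,
    cfg: RemaConfig | None = None,
) -> tuple[Hypnogram, RemaResult, float]:
    """Full REM-A pass: threshold, direct detection, flanked-WAKE rescoring.

    Returns the annotated hypnogram, the summary, and the threshold used.
    The two detection routes commute, so their order does not matter.
    """
    cfg = cfg or RemaConfig()
    if cfg.absolute_threshold is not None:
        th = float(cfg.absolute_threshold)
    else:
        th = atonia_threshold(
            h,
            emg_rms,
            percentile=cfg.percentile,
            factor=cfg.factor,
            margin=cfg.margin,
            floor=cfg.floor,
            min_rems_epochs=cfg.min_rems_epochs,
        )
    out = detect_rema_in_rems(h, emg_rms, th)
    out = rescore_flanked_wake(
        out,
        emg_rms,
        features,
        th,
        theta_delta_threshold=cfg.theta_delta_threshold,
        min_flank_epochs=cfg.min_flank_epochs,
        max_run=cfg.max_rescore_run,
        strict_eeg=cfg.strict_eeg,
    )
    return out, rema_summary(out), th
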