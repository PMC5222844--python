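"""Per-epoch Welch power spectral density and band powers.

Each 4-s epoch of the 125 Hz EEG (500 samples) is turned into a one-sided
Welch PSD with 2-s Hamming-windowed segments at 50% overlap (three segments
per epoch). That segment length forces a 0.5 Hz frequency grid from 0 to
62.5 Hz, which is the resolution at which spectra are reported throughout.

Band powers are trapezoidal integrals of the density over named bands.
Murine band edges differ from the human convention; the defaults used here
are δ 0.5–5, θ 5–9, α 9–12, μ 12–16, β 16–30 Hz, and slow-wave activity
(SWA) is the 0.5–5 Hz integral during NREMS. All edges are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

from . import io_formats
from .core import ARTIFACT, Hypnogram, Recording
from .errors import IntegrityError, UndefinedResultError


class BandDefinition(NamedTuple):
    name: str
    lo: float
    hi: float


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 5.0),
    "theta": BandDefinition("theta", 5.0, 9.0),
    "alpha": BandDefinition("alpha", 9.0, 12.0),
    "mu": BandDefinition("mu", 12.0, 16.0),
    "beta": BandDefinition("beta", 16.0, 30.0),
    "swa": BandDefinition("swa", 0.5, 5.0),
}


@dataclass
class EpochSpectrum:
    """One-sided PSD on the 0.5 Hz grid, power in µV²/Hz."""

    freqs: np.ndarray
    power: np.ndarray


def _welch(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(2.0 * fs))  # 2-s segments -> 0.5 Hz bins
    return signal.welch(
        epochs,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=-1,
    )


def psd_per_epoch(epochs: np.ndarray, fs: float = 125.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of each row of ``epochs`` (shape ``(n_epochs, n_samples)``).

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(n_epochs, n_freqs)``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    expected = int(round(4.0 * fs))
    if epochs.shape[-1] != expected:
        raise IntegrityError(
            f"epochs must hold {expected} samples (4 s at {fs} Hz), "
            f"got {epochs.shape[-1]}"
        )
    return _welch(epochs, fs)


def epoch_psd(epoch: np.ndarray, fs: float = 125.0) -> EpochSpectrum:
    """Welch PSD of a single 4-s epoch (500 samples at 125 Hz)."""
    freqs, power = psd_per_epoch(np.asarray(epoch, dtype=float)[None, :], fs)
    return EpochSpectrum(freqs=freqs, power=power[0])


def band_power(
    spectrum: EpochSpectrum | tuple[np.ndarray, np.ndarray],
    band: BandDefinition | tuple[float, float] | str,
) -> float | np.ndarray:
    """Trapezoidal integral of the density over ``[lo, hi]`` (µV²).

    Accepts a single spectrum or a batch ``(freqs, psd_2d)``; band may be a
    :class:`BandDefinition`, a ``(lo, hi)`` pair, or a default band name.
    """
    if isinstance(spectrum, EpochSpectrum):
        freqs, power = spectrum.freqs, spectrum.power
    else:
        freqs, power = spectrum
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    lo, hi = (band.lo, band.hi) if isinstance(band, BandDefinition) else band
    if not (freqs[0] <= lo < hi <= freqs[-1] + 1e-9):
        raise IntegrityError(
            f"band [{lo}, {hi}] outside the frequency grid "
            f"[{freqs[0]}, {freqs[-1]}]"
        )
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    out = np.trapezoid(power[..., mask], freqs[mask], axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def recording_epoch_psds(
    rec: Recording, channel: int = 0, epoch_len: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample one EEG channel to 125 Hz and return per-epoch Welch PSDs."""
    x = io_formats.downsample_to_analysis_rate(rec.eeg[channel], rec.fs)
    fs = io_formats.ANALYSIS_FS
    spe = int(round(fs * epoch_len))
    n_epochs = x.shape[0] // spe
    epochs = x[: n_epochs * spe].reshape(n_epochs, spe)
    return psd_per_epoch(epochs, fs)


def _select_epochs(h: Hypnogram, state: str, period: str | None, lights_off_at: float) -> np.ndarray:
    mask = (h.states == state) & ~h.flags[ARTIFACT]
    if period is not None:
        inactive = h.start_times < lights_off_at
        mask &= inactive if period == "inactive" else ~inactive
    return mask


def state_spectrum(
    rec: Recording,
    h: Hypnogram,
    state: str,
    period: str | None = None,
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean (± SEM) PSD over the artifact-free epochs of one state/period.

    Returns ``(freqs, mean, sem, n_epochs)``; raises
    :class:`UndefinedResultError` when no epoch qualifies.
    """
    freqs, psds = recording_epoch_psds(rec, channel=channel, epoch_len=h.epoch_len)
    mask = _select_epochs(h, state, period, rec.lights_off_at)[: psds.shape[0]]
    n = int(mask.sum())
    if n == 0:
        raise UndefinedResultError(
            f"no artifact-free {state} epochs in period {period!r}"
        )
    sel = psds[mask]
    mean = sel.mean(axis=0)
    sem = sel.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return freqs, mean, sem, n


def cohort_state_spectrum(
    pairs: Sequence[tuple[Recording, Hypnogram]],
    state: str,
    period: str | None = None,
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Animal-first group spectrum: average per-epoch PSDs within each animal,
    then across animals (SEM across animals). Animals with no qualifying
    epochs are skipped; raises if none qualifies at all."""
    per_animal = []
    freqs = None
    for rec, h in pairs:
        try:
            freqs, mean, _, _ = state_spectrum(rec, h, state, period, channel)
        except UndefinedResultError:
            continue
        per_animal.append(mean)
    if not per_animal:
        raise UndefinedResultError(
            f"no animal has artifact-free {state} epochs in period {period!r}"
        )
    stack = np.vstack(per_animal)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return freqs, mean, sem, n
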