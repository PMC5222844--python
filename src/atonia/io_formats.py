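"""Reading/writing recordings and hypnograms; resampling to the analysis rate.

Signals are stored as EDF (European Data Format), the de-facto standard for
polysomnography, with a documented CSV fallback used mainly in tests. EDF is
read through :mod:`mne`; writing uses a minimal 16-bit EDF writer implemented
here. Hypnograms travel as a small CSV dialect with one row per 4-s epoch.

Analysis runs on EEG downsampled from the 250 Hz acquisition rate to 125 Hz;
:func:`downsample_to_analysis_rate` applies a zero-phase FIR low-pass
(cutoff 55 Hz) before taking every second sample, so epoch boundaries are not
shifted and content above the new Nyquist (62.5 Hz) is strongly suppressed.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import FLAG_NAMES, STATES, Hypnogram, Recording
from .errors import FormatError, IntegrityError

HYPNOGRAM_HEADER = ["epoch", "start_s", "state", "flags"]

ANALYSIS_FS = 125.0
_FIR_NUMTAPS = 129
_FIR_CUTOFF_FRACTION = 55.0 / 125.0  # cutoff relative to the output rate


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording(
    path,
    format: str | None = None,
    lights_off_at: float | None = None,
    animal_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Read a Recording from EDF or CSV.

    Channels are identified by label convention: labels containing ``EEG``
    are EEG channels (>=1 required), labels containing ``EMG`` the single EMG
    channel. EDF stores no lights schedule, so ``lights_off_at`` (seconds) and
    the animal/group metadata can be supplied here; the CSV fallback embeds
    them in its header comment.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path)
    else:
        raise FormatError(f"unknown recording format {format!r}")
    if lights_off_at is not None:
        rec.lights_off_at = float(lights_off_at)
    if animal_id is not None:
        rec.animal_id = animal_id
    if group is not None:
        rec.group = group
    if not 0.0 <= rec.lights_off_at <= rec.duration + 1e-9:
        raise IntegrityError("lights_off_at outside the recorded session")
    return rec


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    names = raw.ch_names
    eeg_idx = [i for i, n in enumerate(names) if "EEG" in n.upper()]
    emg_idx = [i for i, n in enumerate(names) if "EMG" in n.upper()]
    if not eeg_idx:
        raise FormatError(f"no EEG channel in {path} (labels: {names})")
    if not emg_idx:
        raise FormatError(f"no EMG channel in {path} (labels: {names})")
    if len(emg_idx) > 1:
        raise FormatError(f"expected exactly 1 EMG channel, found {len(emg_idx)}")
    data = raw.get_data() * 1e6  # mne holds voltage channels in V; we use µV
    return Recording(
        eeg=data[eeg_idx],
        emg=data[emg_idx[0]],
        fs=float(raw.info["sfreq"]),
        animal_id=path.stem,
    )


def write_recording_edf(rec: Recording, path) -> None:
    """Write a Recording as plain 16-bit EDF (1-s data records).

    The session is truncated to whole seconds; physical extrema are taken
    per channel, so samples survive a round trip to within one quantization
    step of the 16-bit digital range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    labels = [f"EEG {i + 1}" for i in range(rec.n_channels)] + ["EMG"]
    chans = [rec.eeg[i] for i in range(rec.n_channels)] + [rec.emg]
    ns = len(labels)

    def fixed(value, width) -> bytes:
        s = f"{value}"
        if len(s) > width:
            s = s[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            fixed("0", 8),
            fixed("X", 80),
            fixed(f"{rec.animal_id} {rec.group}"[:80], 80),
            fixed("01.01.01", 8),
            fixed("00.00.00", 8),
            fixed(256 * (ns + 1), 8),
            fixed("", 44),
            fixed(n_records, 8),
            fixed(1, 8),
            fixed(ns, 4),
        ]
    )
    phys_min, phys_max, scaled = [], [], []
    for x in chans:
        x = x[: n_records * spr]
        amax = float(np.max(np.abs(x))) if x.size else 1.0
        amax = max(amax, 1e-6)
        pm = float(f"{amax * 1.001:.6g}")  # must survive the 8-char ASCII field
        phys_min.append(-pm)
        phys_max.append(pm)
        dig = np.round(x / pm * 32767.0).astype("<i2")
        scaled.append(dig)
    for items, width in [
        (labels, 16),
        ([""] * ns, 80),
        (["uV"] * ns, 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([-32768] * ns, 8),
        ([32767] * ns, 8),
        ([""] * ns, 80),
        ([spr] * ns, 8),
        ([""] * ns, 32),
    ]:
        header += b"".join(fixed(v, width) for v in items)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for dig in scaled:
                fh.write(struct.pack(f"<{spr}h", *dig[r * spr : (r + 1) * spr]))


def write_recording_csv(rec: Recording, path) -> None:
    """CSV fallback: a ``#``-prefixed JSON metadata line, then one column per
    channel (``eeg_0`` ... ``emg``)."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "lights_off_at": rec.lights_off_at,
        "animal_id": rec.animal_id,
        "group": rec.group,
    }
    cols = {f"eeg_{i}": rec.eeg[i] for i in range(rec.n_channels)}
    cols["emg"] = rec.emg
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def _read_csv(path: Path) -> Recording:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing metadata comment line")
        try:
            meta = json.loads(first.lstrip("# "))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: bad metadata line: {exc}") from exc
        df = pd.read_csv(fh)
    eeg_cols = [c for c in df.columns if c.startswith("eeg")]
    if not eeg_cols or "emg" not in df.columns:
        raise FormatError(f"{path}: need >=1 'eeg_*' column and an 'emg' column")
    return Recording(
        eeg=df[eeg_cols].to_numpy().T,
        emg=df["emg"].to_numpy(),
        fs=float(meta["fs"]),
        lights_off_at=float(meta.get("lights_off_at", 0.0)),
        animal_id=str(meta.get("animal_id", path.stem)),
        group=str(meta.get("group", "unlabeled")),
    )


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path) -> None:
    """Write the hypnogram CSV dialect.

    Columns: ``epoch`` (0-based), ``start_s``, ``state``, ``flags``
    (semicolon-joined annotation names, empty if none).
    """
    rows = []
    times = h.start_times
    for i in range(h.n_epochs):
        flags = ";".join(name for name in FLAG_NAMES if h.flags[name][i])
        rows.append((i, times[i], h.states[i], flags))
    df = pd.DataFrame(rows, columns=HYPNOGRAM_HEADER)
    df.to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    if list(df.columns) != HYPNOGRAM_HEADER:
        raise FormatError(
            f"{path}: expected header {HYPNOGRAM_HEADER}, got {list(df.columns)}"
        )
    states = df["state"].to_numpy()
    bad = set(states) - set(STATES)
    if bad:
        raise FormatError(f"{path}: unknown state token(s) {sorted(bad)}")
    n = len(df)
    flags = {name: np.zeros(n, dtype=bool) for name in FLAG_NAMES}
    for i, cell in enumerate(df["flags"]):
        for token in str(cell).split(";"):
            token = token.strip()
            if not token:
                continue
            if token not in flags:
                raise FormatError(f"{path}: unknown flag token {token!r}")
            flags[token][i] = True
    start = df["start_s"].astype(float).to_numpy()
    epoch_len = float(start[1] - start[0]) if n > 1 else 4.0
    return Hypnogram(
        states=states,
        flags=flags,
        epoch_len=epoch_len,
        epoch0_time=float(start[0]) if n else 0.0,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def downsample_to_analysis_rate(
    x: np.ndarray, fs_in: float = 250.0, fs_out: float = ANALYSIS_FS
) -> np.ndarray:
    """Downsample by an integer factor with a zero-phase anti-alias FIR.

    The low-pass (Hamming-windowed FIR, 129 taps, cutoff 55 Hz at the nominal
    250->125 Hz setting) is applied forward-backward, then every ``q``-th
    sample is kept. Odd-length inputs drop the trailing sample, so a signal of
    ``n`` samples yields ``n // q``.
    """
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise FormatError(
            f"unsupported rate ratio {fs_in}/{fs_out}: must be a whole number"
        )
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_out = n // q
    if q == 1:
        return x[..., :n_out].copy()
    cutoff = _FIR_CUTOFF_FRACTION * fs_out
    taps = signal.firwin(_FIR_NUMTAPS, cutoff, fs=fs_in, window="hamming")
    padlen = min(3 * (_FIR_NUMTAPS - 1), n - 1)
    y = signal.filtfilt(taps, 1.0, x, axis=-1, padlen=padlen)
    idx = np.arange(n_out) * q
    return y[..., idx]
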