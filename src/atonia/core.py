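"""Core containers: multichannel recordings and epoch-wise hypnograms.

Vigilance is scored on non-overlapping 4-s epochs into three states —
WAKE, NREMS (non-REM sleep) and REMS (REM sleep). A :class:`Hypnogram`
carries one state per epoch plus boolean annotation layers for
micro-arousals, REM-without-atonia (REM-A) and artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .errors import IntegrityError

WAKE = "WAKE"
NREMS = "NREMS"
REMS = "REMS"
STATES = (WAKE, NREMS, REMS)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

MICRO_AROUSAL = "MICRO_AROUSAL"
REM_A = "REM_A"
ARTIFACT = "ARTIFACT"
TRANSIENT = "TRANSIENT"
FLAG_NAMES = (MICRO_AROUSAL, REM_A, ARTIFACT, TRANSIENT)

EPOCH_LEN_S = 4.0


@dataclass
class Recording:
    """A single-session EEG/EMG recording.

    Parameters
    ----------
    eeg
        EEG traces in µV, shape ``(n_channels, n_samples)`` (a 1-D array is
        promoted to one channel).
    emg
        Neck-EMG trace in µV, shape ``(n_samples,)``.
    fs
        Sampling rate in Hz (nominal 250).
    lights_off_at
        Offset in seconds of the light->dark transition within the session.
        The session is assumed to start at lights-on, so epochs before this
        offset belong to the inactive (rest) period of the nocturnal animal.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 250.0
    lights_off_at: float = 0.0
    animal_id: str = "animal"
    group: str = "unlabeled"

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.emg = np.asarray(self.emg, dtype=float).ravel()
        if self.fs <= 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.fs}")
        if self.eeg.shape[1] != self.emg.shape[0]:
            raise IntegrityError(
                "channel length mismatch: "
                f"EEG has {self.eeg.shape[1]} samples, EMG has {self.emg.shape[0]}"
            )
        if not 0.0 <= self.lights_off_at <= self.duration + 1e-9:
            raise IntegrityError(
                f"lights_off_at={self.lights_off_at} outside session [0, {self.duration}]"
            )

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples / self.fs


class Run(NamedTuple):
    """A maximal run of consecutive equal-state epochs."""

    state: str
    start: int
    length: int


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels with annotation layers.

    ``flags`` maps each annotation name to a boolean array over epochs.
    The REM_A layer may only be set on epochs whose state is REMS.
    """

    states: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    epoch_len: float = EPOCH_LEN_S
    epoch0_time: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U5")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise IntegrityError(f"unknown state token(s): {sorted(bad)}")
        n = self.states.shape[0]
        for name in FLAG_NAMES:
            if name not in self.flags:
                self.flags[name] = np.zeros(n, dtype=bool)
            else:
                self.flags[name] = np.asarray(self.flags[name], dtype=bool)
                if self.flags[name].shape[0] != n:
                    raise IntegrityError(f"flag layer {name!r} length mismatch")
        if np.any(self.flags[REM_A] & (self.states != REMS)):
            raise IntegrityError("REM_A flag set on a non-REMS epoch")
        if self.epoch_len <= 0:
            raise IntegrityError("epoch_len must be positive")

    @property
    def n_epochs(self) -> int:
        return self.states.shape[0]

    @property
    def start_times(self) -> np.ndarray:
        """Start time (s) of each epoch; epochs are half-open [t, t+epoch_len)."""
        return self.epoch0_time + np.arange(self.n_epochs) * self.epoch_len

    def copy(self) -> "Hypnogram":
        return Hypnogram(
            states=self.states.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
            epoch_len=self.epoch_len,
            epoch0_time=self.epoch0_time,
        )

    def runs(self) -> list[Run]:
        """Maximal runs of equal state, in order, tiling the hypnogram."""
        if self.n_epochs == 0:
            return []
        change = np.flatnonzero(self.states[1:] != self.states[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [self.n_epochs]))
        return [
            Run(str(self.states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)
        ]

    def __iter__(self) -> Iterator[str]:
        return iter(self.states)

    def __len__(self) -> int:
        return self.n_epochs


def hypnogram_from_tokens(tokens, epoch_len: float = EPOCH_LEN_S, epoch0_time: float = 0.0) -> Hypnogram:
    """Build a Hypnogram from short tokens, e.g. ``list("WWNNR")``.

    Accepts W/N/R single-letter tokens or full state names.
    """
    short = {"W": WAKE, "N": NREMS, "R": REMS}
    states = [short.get(t, t) for t in tokens]
    return Hypnogram(np.array(states), epoch_len=epoch_len, epoch0_time=epoch0_time)
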